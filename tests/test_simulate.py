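"""The synthetic-data generator: determinism, planted structure, noise model."""

import numpy as np
import pytest

import pioneerkit as pk
from pioneerkit.errors import ConfigError, SimulationError
from pioneerkit.genome import reverse_complement
from pioneerkit.simulate import (
    generate_chromhmm,
    generate_counts,
    generate_genome,
    generate_peaksets,
    generate_tissue_table,
    plant_sites,
    tissue_truth_sets,
)

from conftest import small_config


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def test_genome_deterministic_given_seed():
    cfg = pk.SimConfig(seed=1, chrom_sizes={"chr1": 100_000}, gc_content=0.5)
    g1 = generate_genome(cfg)
    g2 = generate_genome(cfg)
    assert g1.sequence("chr1") == g2.sequence("chr1")
    assert len(g1.sequence("chr1")) == 100_000


def test_genome_degenerate_gc_one():
    cfg = pk.SimConfig(seed=2, chrom_sizes={"chr1": 20_000}, gc_content=1.0)
    seq = generate_genome(cfg).sequence("chr1")
    assert set(seq) <= {"G", "C"}


def test_genome_gc_fraction_within_binomial_ci():
    """At 1 Mb the observed GC fraction of a gc=0.4 genome lies within
    0.39-0.41 (far beyond 6 binomial sigmas)."""
    cfg = pk.SimConfig(seed=3, chrom_sizes={"chr1": 1_000_000}, gc_content=0.4)
    seq = generate_genome(cfg).sequence("chr1")
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.39 < gc < 0.41


def test_chromosome_size_validated():
    with pytest.raises(ConfigError):
        pk.SimConfig(chrom_sizes={"chr1": 500})


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _plant(cfg, consensus=False):
    cfg.consensus_motifs = consensus
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    pwms = pk.default_pwms()
    return plant_sites(genome, cfg, pwms, rng), pwms


def test_planted_windows_disjoint_and_exactly_500bp():
    (genome, plan), _ = _plant(small_config(seed=6))
    t = plan.table
    assert ((t["end"] - t["start"]) == 500).all()
    for chrom, sub in t.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].values[1:] >= s["end"].values[:-1]).all()


def test_consensus_planting_matches_string_oracle():
    """With consensus-forcing instances, ledger counts equal naive substring
    counts of the consensus (or its reverse complement) in each window."""
    (genome, plan), pwms = _plant(small_config(seed=7), consensus=True)
    for tf, col in (("FOXA1", "n_foxa1"), ("HNF4A", "n_hnf4a")):
        cons = pwms[tf].consensus()
        rc = reverse_complement(cons)
        for row in plan.table.itertuples(index=False):
            seq = genome.fetch(row.chrom, row.start, row.end)
            found = seq.count(cons) + (seq.count(rc) if rc != cons else 0)
            assert found >= getattr(row, col)


def test_background_windows_untouched():
    cfg = small_config(seed=8)
    rng = np.random.default_rng(cfg.seed)
    before = generate_genome(cfg, rng)
    pristine = {c: before.sequence(c) for c in before.chroms()}
    after, plan = plant_sites(before, cfg, pk.default_pwms(), rng)
    for row in plan.of_class("background").itertuples(index=False):
        assert (after.fetch(row.chrom, row.start, row.end)
                == pristine[row.chrom][row.start:row.end])


def test_planting_fails_when_genome_too_small():
    cfg = small_config(seed=9, chrom_sizes={"chr1": 10_000})
    with pytest.raises(SimulationError, match="disjoint"):
        _plant(cfg)


def test_multiplicities_within_configured_ranges():
    cfg = small_config(seed=10)
    (_, plan), _ = _plant(cfg)
    for row in plan.table.itertuples(index=False):
        for tf, col in (("FOXA1", "n_foxa1"), ("HNF4A", "n_hnf4a")):
            lo, hi = cfg.motif_multiplicity.get(tf, {}).get(row.cls, (0, 0))
            assert lo <= getattr(row, col) <= hi


# ---------------------------------------------------------------------------
# peak sets
# ---------------------------------------------------------------------------

def test_noise_free_replicates_identical_and_class_membership():
    cfg = small_config(seed=11).noise_free()
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    _, plan = plant_sites(genome, cfg, pk.default_pwms(), rng)
    tracks = generate_peaksets(plan, cfg, rng)
    for track, (r1, r2) in tracks.items():
        assert r1 == r2
    # one CB site: in both double tracks, absent from singles and ATAC-pre
    cb = plan.of_class("CB").iloc[0]
    for track, expect in [
        ("foxa1_double", True), ("hnf4a_double", True),
        ("foxa1_single", False), ("hnf4a_single", False),
        ("atac_pre", False), ("atac_post", True),
    ]:
        present = tracks[track][0].overlaps_any(cb.chrom, cb.start, cb.end)
        assert present is expect, track


def test_jitter_dropout_retention_binomial():
    """After replicate merging a peak survives iff kept in both replicates:
    retained fraction ~ (1 - dropout)^2 within 3 binomial sigmas."""
    import pandas as pd
    from pioneerkit.simulate import SitePlan

    n = 1000
    rows = [
        {"site_id": f"s{i}", "chrom": "chr1", "start": 800 * i, "end": 800 * i + 500,
         "cls": "foxa1_inaccessible", "n_foxa1": 0, "n_hnf4a": 0, "gene_id": ""}
        for i in range(n)
    ]
    plan = SitePlan(pd.DataFrame(rows))
    cfg = pk.SimConfig(seed=12, chrom_sizes={"chr1": 800 * n + 1000},
                       jitter_sd=10.0, dropout=0.1,
                       site_counts={"foxa1_inaccessible": n},
                       n_activated=0, tissue_set_sizes={})
    tracks = generate_peaksets(plan, cfg, np.random.default_rng(12))
    merged = pk.merge_replicates(*tracks["foxa1_single"])
    p = 0.9**2
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(len(merged) / n - p) < 3 * sd


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def test_counts_nb_mean_oracle():
    """Planted lfc=3 from baseline 5: induced sample mean near 40."""
    cfg = pk.SimConfig(seed=13, chrom_sizes={"chr1": 100_000},
                       site_counts={"FP": 1}, n_genes=1000, n_activated=500,
                       activated_lfc=3.0, activated_base_mean=5.0,
                       tissue_set_sizes={"liver": 500})
    cm, truth = generate_counts(cfg, np.random.default_rng(13))
    assert len(truth) == 500
    act = cm.counts.loc[sorted(truth)]
    induced = act[[s for s in cm.counts.columns if s.startswith("induced")]]
    uninduced = act[[s for s in cm.counts.columns if s.startswith("uninduced")]]
    assert induced.values.mean() == pytest.approx(40.0, rel=0.05)
    assert uninduced.values.mean() == pytest.approx(5.0, rel=0.05)


def test_counts_large_dispersion_approaches_planted_means():
    cfg = pk.SimConfig(seed=14, chrom_sizes={"chr1": 100_000},
                       site_counts={"FP": 1}, n_genes=2000, n_activated=0,
                       nb_dispersion=1e6, baseline_sigma=0.0,
                       tissue_set_sizes={})
    cm, _ = generate_counts(cfg, np.random.default_rng(14))
    assert cm.counts.values.mean() == pytest.approx(cfg.nb_mean, rel=0.05)


def test_zero_lfc_yields_empty_truth_and_no_systematic_shift():
    cfg = pk.SimConfig(seed=15, chrom_sizes={"chr1": 100_000},
                       site_counts={"FP": 1}, n_genes=400, n_activated=50,
                       activated_lfc=0.0, tissue_set_sizes={"liver": 60})
    cm, truth = generate_counts(cfg, np.random.default_rng(15))
    assert truth == set()
    diff = pk.differential_table(cm)
    assert abs(diff["log2fc"].mean()) < 0.15


# ---------------------------------------------------------------------------
# tissue table
# ---------------------------------------------------------------------------

def test_tissue_boundary_four_vs_three_nine():
    for fold, expect in ((4.0, True), (3.9, False)):
        cfg = pk.SimConfig(seed=16, chrom_sizes={"chr1": 100_000},
                           site_counts={"FP": 1}, n_genes=100, n_activated=10,
                           tissue_fold=fold, tissue_set_sizes={"liver": 20})
        tsets = tissue_truth_sets(cfg)
        table = generate_tissue_table(cfg, tsets, np.random.default_rng(16))
        recovered = pk.tissue_enriched_genes(table, "liver", fold=4.0).genes
        hit = tsets["liver"] <= recovered
        assert hit is expect


def test_no_spurious_tissue_enrichment():
    cfg = pk.SimConfig(seed=17, chrom_sizes={"chr1": 100_000},
                       site_counts={"FP": 1}, n_genes=500, n_activated=10,
                       tissue_set_sizes={"liver": 30, "intestine": 20})
    tsets = tissue_truth_sets(cfg)
    table = generate_tissue_table(cfg, tsets, np.random.default_rng(17))
    planted = set().union(*tsets.values())
    for tissue in table.columns:
        got = pk.tissue_enriched_genes(table, tissue).genes
        assert got - planted == set()


# ---------------------------------------------------------------------------
# segmentation + full-dataset determinism
# ---------------------------------------------------------------------------

def test_chromhmm_tiles_genome_without_overlap():
    cfg = small_config(seed=18)
    ds = pk.simulate_dataset(cfg)
    segs = list(ds.chromhmm)
    by_chrom = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda v: v.start)
        assert ivs[0].start == 0
        assert ivs[-1].end == cfg.chrom_sizes[chrom]
        for a, b in zip(ivs, ivs[1:]):
            assert a.end == b.start  # gap- and overlap-free tiling


def test_full_dataset_deterministic(tmp_path):
    from pioneerkit.pipeline import write_dataset

    cfg = small_config(seed=19)
    m1 = write_dataset(pk.simulate_dataset(cfg), tmp_path / "a")
    m2 = write_dataset(pk.simulate_dataset(cfg), tmp_path / "b")
    assert m1["files"] == m2["files"]
    cfg2 = small_config(seed=20)
    m3 = write_dataset(pk.simulate_dataset(cfg2), tmp_path / "c")
    assert m1["files"]["genome.fa"] != m3["files"]["genome.fa"]
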