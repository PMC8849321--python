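"""End-to-end orchestration: simulate a dataset, analyze it, summarize.

``cmd_simulate`` writes a synthetic dataset directory (FASTA genome, BED peak
replicates, counts/tissue TSVs, the ground-truth site ledger, PWMs, config
echo and a checksum manifest).  ``cmd_analyze`` runs the full analysis on a
dataset directory -- replicate merging, accessibility and opening calls,
co-binding taxonomy, chromatin-state profiling, gene attribution, activation
and tissue enrichment, motif counting, and the affinity-model ROC suite --
writing one TSV/JSON per stage plus a run record.  When the dataset carries a
site ledger, a recovery report scoring the classification against the
planted truth is produced as well.  ``cmd_report`` folds the stage outputs
into a single summary JSON.

Every stage is deterministic given the dataset and the run seed; rerunning
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity import binding_prediction_experiment, compare_groups
from .binding_class import (
    classify_accessibility,
    classify_cobinding,
    chromhmm_fractions,
    cobound_sites,
    site_classification_table,
)
from .errors import UsageError
from .expression import (
    CountMatrix,
    call_activated,
    differential_table,
    enrichment_report,
    tissue_enriched_genes,
)
from .genome import Genome
from .intervals import (
    GeneAnnotation,
    PeakSet,
    attribute_to_genes,
    merge_replicates,
    midpoint_window,
    read_bed,
    write_bed,
)
from .motifs import PWM, build_score_null, motif_count, read_jaspar, write_jaspar
from .simulate import (
    ACCESSIBLE_CLASSES,
    CLASS_TRACKS,
    COBOUND_CLASSES,
    SimConfig,
    SimDataset,
    SitePlan,
    TRACKS,
    simulate_dataset,
)

__all__ = ["RunConfig", "cmd_simulate", "cmd_analyze", "cmd_report", "recovery_report"]


@dataclass
class RunConfig:
    """Analysis thresholds and paths; defaults are the study constants."""

    data_dir: str
    out_dir: str
    seed: int = 0
    motif_p: float = 1e-3
    lfc_min: float = 1.0
    base_max: float = 50.0
    tissue_fold: float = 4.0
    half_window_single: int = 25_000
    half_window_cobound: int = 50_000
    window: int = 500
    aggregate_mode: str = "sum"

    def __post_init__(self) -> None:
        for name in ("motif_p", "lfc_min", "base_max", "tissue_fold",
                     "half_window_single", "half_window_cobound", "window"):
            if getattr(self, name) <= 0:
                raise UsageError(f"RunConfig.{name} must be positive")
        if self.aggregate_mode not in ("sum", "count"):
            raise UsageError("aggregate_mode must be 'sum' or 'count'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path) -> dict:
    files = sorted(
        p.relative_to(outdir).as_posix()
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {"files": {f: _sha256(outdir / f) for f in files}}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def write_dataset(ds: SimDataset, outdir) -> dict:
    """Write every artifact of a simulated dataset; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.genome.write_fasta(outdir / "genome.fa")
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for track, (rep1, rep2) in ds.peaksets.items():
        write_bed(rep1, peaks_dir / f"{track}_rep1.bed")
        write_bed(rep2, peaks_dir / f"{track}_rep2.bed")
    pwm_dir = outdir / "pwms"
    pwm_dir.mkdir(exist_ok=True)
    for tf, pwm in ds.pwms.items():
        write_jaspar(pwm, pwm_dir / f"{tf}.jaspar", scale=100.0)
    ds.genes.write_tsv(outdir / "genes.tsv")
    ds.counts.write_tsv(outdir / "counts.tsv")
    # .17g + round_trip parsing on the read side keeps the planted fourfold
    # boundary exact through serialization
    ds.tissue_table.to_csv(outdir / "tissue.tsv", sep="\t",
                           float_format=lambda v: format(v, ".17g"))
    ds.plan.write_tsv(outdir / "site_plan.tsv")
    write_bed(ds.chromhmm, outdir / "chromhmm.bed")
    with open(outdir / "activated_truth.txt", "w") as fh:
        for gid in sorted(ds.activated_truth):
            fh.write(gid + "\n")
    ds.config.to_yaml(outdir / "config.yaml")
    return _write_manifest(outdir)


def cmd_simulate(config: SimConfig, outdir, force: bool = False) -> dict:
    """Generate a synthetic dataset directory; refuses to overwrite unless
    ``force``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise UsageError(f"output directory {outdir} is non-empty (use force)")
    ds = simulate_dataset(config)
    return write_dataset(ds, outdir)


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _require(path: Path) -> Path:
    if not path.exists():
        raise UsageError(f"missing input file: {path}")
    return path


def _load_dataset_dir(data_dir: Path):
    genome = Genome.read_fasta(_require(data_dir / "genome.fa"))
    tracks: Dict[str, Tuple[PeakSet, PeakSet]] = {}
    for track in TRACKS:
        rep1 = read_bed(_require(data_dir / "peaks" / f"{track}_rep1.bed"), label=track)
        rep2 = read_bed(_require(data_dir / "peaks" / f"{track}_rep2.bed"), label=track)
        tracks[track] = (rep1, rep2)
    # score null calibrated on the genome's own base composition, so random
    # genomic sequence really does produce ~2*(L-w+1)*p false hits
    composition = genome.base_composition()
    pwms = {
        tf: read_jaspar(_require(data_dir / "pwms" / f"{tf}.jaspar"),
                        background=composition)
        for tf in ("FOXA1", "HNF4A")
    }
    genes = GeneAnnotation.read_tsv(_require(data_dir / "genes.tsv"))
    counts = CountMatrix.read_tsv(_require(data_dir / "counts.tsv"))
    tissue = pd.read_csv(_require(data_dir / "tissue.tsv"), sep="\t",
                         index_col="gene", float_precision="round_trip")
    chromhmm_path = data_dir / "chromhmm.bed"
    chromhmm = read_bed(chromhmm_path) if chromhmm_path.exists() else None
    plan_path = data_dir / "site_plan.tsv"
    plan = SitePlan.read_tsv(plan_path) if plan_path.exists() else None
    return genome, tracks, pwms, genes, counts, tissue, chromhmm, plan


def recovery_report(plan: SitePlan, merged: Mapping[str, PeakSet]) -> dict:
    """Score recovered classifications against the planted ledger.

    For every planted non-background site the report checks (a) presence of
    an overlapping merged peak in each track the class implies, (b) the
    accessibility and opened flags of the recovered site, and (c) for
    co-bound classes, the recovered FP/HP/BOTH/CB label.  A site counts as
    recovered only when every applicable check passes.  Background windows
    overlapping any merged binding peak are reported as false positives.
    """
    atac_pre, atac_post = merged["atac_pre"], merged["atac_post"]
    cob = cobound_sites(merged["foxa1_double"], merged["hnf4a_double"])
    cob_labels = classify_cobinding(cob, merged["foxa1_single"], merged["hnf4a_single"])
    label_of = {
        (iv.chrom, iv.start, iv.end): lab for iv, lab in zip(cob, cob_labels)
    }
    n_total = n_correct = 0
    check_fail = {"presence": 0, "accessibility": 0, "opened": 0, "cobind": 0}
    for row in plan.table.itertuples(index=False):
        cls = row.cls
        if cls == "background":
            continue
        n_total += 1
        ok = True
        for track in CLASS_TRACKS[cls]:
            if not merged[track].overlaps_any(row.chrom, row.start, row.end):
                ok = False
                check_fail["presence"] += 1
                break
        if not ok:
            continue
        # the recovered site interval used for accessibility calls
        if cls in COBOUND_CLASSES:
            matches = cob.query(row.chrom, row.start, row.end)
            if not matches:
                check_fail["presence"] += 1
                continue
            site_iv = matches[0]
            if label_of[(site_iv.chrom, site_iv.start, site_iv.end)] != cls:
                check_fail["cobind"] += 1
                continue
        else:
            track = CLASS_TRACKS[cls][0]
            site_iv = merged[track].query(row.chrom, row.start, row.end)[0]
        accessible = atac_pre.overlap_interval(site_iv)
        opened = (not accessible) and atac_post.overlap_interval(site_iv)
        want_accessible = cls in ACCESSIBLE_CLASSES
        if accessible != want_accessible:
            check_fail["accessibility"] += 1
            continue
        if opened != (not want_accessible):
            check_fail["opened"] += 1
            continue
        n_correct += 1
    bg = plan.of_class("background")
    binding_tracks = ("foxa1_single", "hnf4a_single", "foxa1_double", "hnf4a_double")
    bg_hits = sum(
        1
        for row in bg.itertuples(index=False)
        if any(merged[t].overlaps_any(row.chrom, row.start, row.end)
               for t in binding_tracks)
    )
    return {
        "n_planted": n_total,
        "n_recovered": n_correct,
        "recovery_rate": n_correct / n_total if n_total else 1.0,
        "failures": check_fail,
        "background_sites": int(len(bg)),
        "background_false_positives": int(bg_hits),
    }


def cmd_analyze(cfg: RunConfig) -> dict:
    """Run every analysis stage on a dataset directory.

    Returns a dict of the principal in-memory results (also written to
    ``cfg.out_dir``): merged tracks, site tables, enrichment, ROC results and
    the recovery report when ground truth is available.
    """
    data_dir = Path(cfg.data_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, tracks, pwms, genes, counts, tissue, chromhmm, plan = _load_dataset_dir(data_dir)

    # 1. replicate merging
    merged: Dict[str, PeakSet] = {}
    merged_dir = outdir / "merged"
    merged_dir.mkdir(exist_ok=True)
    for track, (rep1, rep2) in tracks.items():
        merged[track] = merge_replicates(rep1, rep2, label=track)
        write_bed(merged[track], merged_dir / f"{track}.bed")

    atac_pre, atac_post = merged["atac_pre"], merged["atac_post"]
    nulls = {tf: build_score_null(pwm) for tf, pwm in pwms.items()}

    # 2. accessibility / opening of single-expression binding sites
    single_tables: Dict[str, pd.DataFrame] = {}
    for tf, track in (("FOXA1", "foxa1_single"), ("HNF4A", "hnf4a_single")):
        table = site_classification_table(merged[track], atac_pre, atac_post,
                                          segments=chromhmm)
        table.insert(0, "tf", tf)
        single_tables[tf] = table
        table.to_csv(outdir / f"sites_{tf}.tsv", sep="\t", index=False)

    # 3. co-binding taxonomy
    cob = cobound_sites(merged["foxa1_double"], merged["hnf4a_double"])
    cob_labels = classify_cobinding(cob, merged["foxa1_single"], merged["hnf4a_single"])
    cob_table = site_classification_table(cob, atac_pre, atac_post,
                                          cobind_labels=cob_labels, segments=chromhmm)
    cob_table.to_csv(outdir / "sites_cobound.tsv", sep="\t", index=False)
    class_counts = {c: int((np.asarray(cob_labels) == c).sum())
                    for c in ("FP", "HP", "BOTH", "CB")}
    class_counts["total"] = len(cob_labels)

    # 4. chromatin-state profile of co-binding classes
    fractions = None
    if chromhmm is not None and len(cob):
        by_class = {
            c: PeakSet([iv for iv, lab in zip(cob, cob_labels) if lab == c])
            for c in ("FP", "HP", "BOTH", "CB")
        }
        by_class = {c: ps for c, ps in by_class.items() if len(ps)}
        fractions = chromhmm_fractions(by_class, chromhmm)
        fractions.to_csv(outdir / "chromhmm_fractions.tsv", sep="\t",
                         index_label="cobind_class")

    # 5. gene attribution
    attribution_rows = []
    for tf, track in (("FOXA1", "foxa1_single"), ("HNF4A", "hnf4a_single")):
        for gid, ps in attribute_to_genes(merged[track], genes,
                                          cfg.half_window_single).items():
            attribution_rows.append({"gene": gid, "track": track, "n_peaks": len(ps)})
    for gid, ps in attribute_to_genes(cob, genes, cfg.half_window_cobound).items():
        attribution_rows.append({"gene": gid, "track": "cobound", "n_peaks": len(ps)})
    attribution = pd.DataFrame(attribution_rows, columns=["gene", "track", "n_peaks"])
    attribution.sort_values(["track", "gene"], inplace=True)
    attribution.to_csv(outdir / "gene_attribution.tsv", sep="\t", index=False)

    # 6. activation and tissue enrichment
    diff = differential_table(counts)
    diff.to_csv(outdir / "differential.tsv", sep="\t", index_label="gene")
    activated = call_activated(diff, lfc_min=cfg.lfc_min, base_max=cfg.base_max)
    with open(outdir / "activated_genes.txt", "w") as fh:
        for gid in sorted(activated):
            fh.write(gid + "\n")
    tissue_sets = [
        tissue_enriched_genes(tissue, t, fold=cfg.tissue_fold) for t in tissue.columns
    ]
    enrichment = enrichment_report(activated, tissue_sets, diff.index)
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    # 7. motif counts around binding sites
    count_rows = []
    site_groups = [
        ("foxa1_single", merged["foxa1_single"], None),
        ("hnf4a_single", merged["hnf4a_single"], None),
        ("cobound", cob, cob_labels),
    ]
    for group, sites, labels in site_groups:
        accessible = classify_accessibility(sites, atac_pre)
        for i, iv in enumerate(sites):
            win, _ = midpoint_window(iv, width=cfg.window,
                                     chrom_size=genome.sizes[iv.chrom])
            row = {
                "group": group,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "accessible": bool(accessible[i]),
                "cobind_class": labels[i] if labels is not None else "",
            }
            for tf, pwm in pwms.items():
                row[f"{tf.lower()}_motifs"] = motif_count(
                    pwm, genome, win, p_thresh=cfg.motif_p, null=nulls[tf]
                )
            count_rows.append(row)
    motif_counts = pd.DataFrame(count_rows)
    motif_counts.to_csv(outdir / "motif_counts.tsv", sep="\t", index=False)

    # 8. group summaries of motif content
    groups: Dict[str, list] = {}
    mc = motif_counts
    for tf, track in (("FOXA1", "foxa1_single"), ("HNF4A", "hnf4a_single")):
        col = f"{tf.lower()}_motifs"
        sub = mc[mc["group"] == track]
        for flag, name in ((True, "accessible"), (False, "inaccessible")):
            vals = sub.loc[sub["accessible"] == flag, col].tolist()
            if vals:
                groups[f"{tf}_{name}"] = vals
    for cls, tf in (("FP", "FOXA1"), ("HP", "HNF4A"), ("CB", "FOXA1")):
        vals = mc.loc[
            (mc["group"] == "cobound") & (mc["cobind_class"] == cls),
            f"{tf.lower()}_motifs",
        ].tolist()
        if vals:
            groups[f"{cls}_{tf}_motifs"] = vals
    summaries = compare_groups(groups)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        outdir / "group_summaries.tsv", sep="\t", index=False
    )

    # 9. affinity-model ROC suite
    single_sites = {
        tf: (merged[track], classify_accessibility(merged[track], atac_pre))
        for tf, track in (("FOXA1", "foxa1_single"), ("HNF4A", "hnf4a_single"))
    }
    rocs = binding_prediction_experiment(
        genome, pwms, single_sites, atac_pre, seed=cfg.seed,
        cobound=cob, cobind_labels=cob_labels,
        window=cfg.window, mode=cfg.aggregate_mode,
    )
    roc_dir = outdir / "roc"
    roc_dir.mkdir(exist_ok=True)
    roc_summary = {}
    for name, roc in rocs.items():
        roc.to_frame().to_csv(roc_dir / f"{name}.tsv", sep="\t", index=False)
        roc_summary[name] = {"auc": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg}
    _json_dump(roc_summary, outdir / "roc_summary.json")

    # 10. recovery against the planted truth, when available
    recovery = None
    if plan is not None:
        recovery = recovery_report(plan, merged)
        _json_dump(recovery, outdir / "recovery.json")

    _json_dump(class_counts, outdir / "cobind_summary.json")
    run_record = {
        "pioneerkit_version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
    }
    _json_dump(run_record, outdir / "run.json")
    _write_manifest(outdir)
    return {
        "merged": merged,
        "cobound": cob,
        "cobind_labels": cob_labels,
        "class_counts": class_counts,
        "single_tables": single_tables,
        "cobound_table": cob_table,
        "chromhmm_fractions": fractions,
        "differential": diff,
        "activated": activated,
        "enrichment": enrichment,
        "motif_counts": motif_counts,
        "group_summaries": summaries,
        "rocs": rocs,
        "recovery": recovery,
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def cmd_report(results_dir) -> dict:
    """Aggregate stage outputs into one summary JSON (written alongside).

    Missing stage outputs are reported as null with a warning entry rather
    than failing.
    """
    results_dir = Path(results_dir)
    summary: dict = {"warnings": []}

    def _load_json(name):
        path = results_dir / name
        if not path.exists():
            summary["warnings"].append(f"missing {name}")
            return None
        with open(path) as fh:
            return json.load(fh)

    def _load_tsv(name):
        path = results_dir / name
        if not path.exists():
            summary["warnings"].append(f"missing {name}")
            return None
        return pd.read_csv(path, sep="\t")

    summary["cobind_class_counts"] = _load_json("cobind_summary.json")
    summary["roc_auc"] = _load_json("roc_summary.json")
    summary["recovery"] = _load_json("recovery.json")
    enr = _load_tsv("enrichment.tsv")
    summary["enrichment"] = enr.to_dict(orient="records") if enr is not None else None
    gs = _load_tsv("group_summaries.tsv")
    summary["group_summaries"] = gs.to_dict(orient="records") if gs is not None else None
    act_path = results_dir / "activated_genes.txt"
    if act_path.exists():
        summary["n_activated"] = sum(1 for _ in open(act_path))
    else:
        summary["warnings"].append("missing activated_genes.txt")
        summary["n_activated"] = None
    _json_dump(summary, results_dir / "summary.json")
    return summary
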