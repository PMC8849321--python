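"""Synthetic datasets with planted ground truth for the whole pipeline.

The generator emulates the experimental design the analysis assumes: two
transcription factors (called FOXA1 and HNF4A throughout) expressed alone and
together in a cell line, with binding tracks for each condition, chromatin
accessibility tracks before and after induction, an RNA count matrix with
planted gene activation, and a tissue expression table with planted
tissue-enriched gene sets.  Every planted binding site is recorded in a
:class:`SitePlan` ledger -- coordinates, class label, planted motif
multiplicities, linked gene -- so downstream classification can be scored
against exact truth.

Site classes and what they imply:

* ``foxa1_accessible`` / ``foxa1_inaccessible`` -- FOXA1-only sites that were
  open / closed before induction (similarly for HNF4A);
* ``FP`` / ``HP`` -- co-bound sites also bound by FOXA1 / HNF4A alone
  (pioneered);
* ``BOTH`` -- co-bound sites bound by each factor alone;
* ``CB``  -- co-bound sites bound by neither factor alone (cooperative);
* ``background`` -- untouched windows, present in no track.

Motif multiplicities per class default to the regime where FOXA1-pioneered
sites carry 2-4 FOXA1 motifs while HNF4A-pioneered sites need 3-6 HNF4A
motifs, reflecting FOXA1's higher intrinsic affinity; cooperative sites carry
at most one motif of either kind.  Motif instances are sampled column-wise
from the PWM (a consensus-forcing mode exists for exact tests), written at
non-overlapping offsets on random strands inside disjoint 500-bp windows.

All randomness flows from one ``numpy`` generator seeded by ``SimConfig.seed``
in a fixed draw order (genome, sites, genes, peaks, counts, tissue table,
segmentation), so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SimulationError
from .expression import CountMatrix
from .genome import Genome, reverse_complement
from .intervals import GenomicInterval, GeneAnnotation, PeakSet
from .motifs import PWM

__all__ = [
    "SimConfig",
    "SitePlan",
    "SimDataset",
    "default_pwms",
    "generate_genome",
    "plant_sites",
    "generate_genes",
    "generate_peaksets",
    "generate_counts",
    "generate_tissue_table",
    "generate_chromhmm",
    "simulate_dataset",
]

SITE_CLASSES = (
    "foxa1_accessible",
    "foxa1_inaccessible",
    "hnf4a_accessible",
    "hnf4a_inaccessible",
    "FP",
    "HP",
    "BOTH",
    "CB",
    "background",
)
COBOUND_CLASSES = ("FP", "HP", "BOTH", "CB")
ACCESSIBLE_CLASSES = ("foxa1_accessible", "hnf4a_accessible")
BOUND_CLASSES = tuple(c for c in SITE_CLASSES if c != "background")

# which binding tracks a site of each class appears in
CLASS_TRACKS: Dict[str, Tuple[str, ...]] = {
    "foxa1_accessible": ("foxa1_single", "foxa1_double"),
    "foxa1_inaccessible": ("foxa1_single", "foxa1_double"),
    "hnf4a_accessible": ("hnf4a_single", "hnf4a_double"),
    "hnf4a_inaccessible": ("hnf4a_single", "hnf4a_double"),
    "FP": ("foxa1_single", "foxa1_double", "hnf4a_double"),
    "HP": ("hnf4a_single", "foxa1_double", "hnf4a_double"),
    "BOTH": ("foxa1_single", "hnf4a_single", "foxa1_double", "hnf4a_double"),
    "CB": ("foxa1_double", "hnf4a_double"),
    "background": (),
}
TRACKS = (
    "foxa1_single",
    "hnf4a_single",
    "foxa1_double",
    "hnf4a_double",
    "atac_pre",
    "atac_post",
)

TISSUES = ("liver", "intestine", "kidney", "lung", "brain", "muscle")


def _default_chrom_sizes() -> Dict[str, int]:
    return {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}


def _default_site_counts() -> Dict[str, int]:
    # co-bound class mix keeps the FP : HP : CB : BOTH proportions of a
    # genome-scale co-binding survey (2023 : 3398 : 2192 : 3789), scaled 1/8
    return {
        "foxa1_accessible": 150,
        "foxa1_inaccessible": 300,
        "hnf4a_accessible": 150,
        "hnf4a_inaccessible": 300,
        "FP": 253,
        "HP": 425,
        "BOTH": 474,
        "CB": 274,
        "background": 200,
    }


def _default_multiplicity() -> Dict[str, Dict[str, Tuple[int, int]]]:
    return {
        "FOXA1": {
            "foxa1_accessible": (1, 2),
            "foxa1_inaccessible": (2, 4),
            "FP": (2, 4),
            "HP": (0, 1),
            "BOTH": (2, 4),
            "CB": (0, 1),
        },
        "HNF4A": {
            "hnf4a_accessible": (1, 3),
            "hnf4a_inaccessible": (3, 6),
            "HP": (3, 6),
            "FP": (0, 1),
            "BOTH": (3, 6),
            "CB": (0, 1),
        },
    }


def _default_tissue_sets() -> Dict[str, int]:
    return {"liver": 242, "intestine": 122}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults define the reference study conditions: a 6-Mb three-chromosome
    genome at 41% GC, ~2,500 planted 500-bp sites with the co-binding class
    mix above, 5,000 genes of which 60 are activated (log2 fold change 3 from
    a silent baseline of ~5 normalized reads), a 242-gene liver and 122-gene
    intestine tissue set, and low replicate noise (10-bp boundary jitter,
    0.5% peak dropout per replicate, i.e. ~99% replicate concordance).
    """

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(default_factory=_default_chrom_sizes)
    gc_content: float = 0.41
    window: int = 500
    site_spacing: int = 300
    site_counts: Dict[str, int] = field(default_factory=_default_site_counts)
    motif_multiplicity: Dict[str, Dict[str, Tuple[int, int]]] = field(
        default_factory=_default_multiplicity
    )
    consensus_motifs: bool = False
    # planted instances are resampled until they would be detected at this
    # scan p-value, so a site planted with k motifs genuinely contains k
    # callable occurrences; None plants unconditioned draws
    min_instance_pvalue: Optional[float] = 1e-3
    jitter_sd: float = 10.0
    dropout: float = 0.005
    n_genes: int = 5000
    n_activated: int = 60
    activated_lfc: float = 3.0
    activated_base_mean: float = 5.0
    nb_mean: float = 200.0
    nb_dispersion: float = 10.0
    baseline_sigma: float = 1.0
    n_uninduced: int = 3
    n_induced: int = 3
    n_tissues: int = 6
    tissue_fold: float = 4.0
    tissue_set_sizes: Dict[str, int] = field(default_factory=_default_tissue_sets)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be non-empty")
        for chrom, size in self.chrom_sizes.items():
            if size < 10_000:
                raise ConfigError(f"chromosome {chrom} too small ({size} < 10000 bp)")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigError("gc_content must lie in [0, 1]")
        if self.window <= 0 or self.window % 2:
            raise ConfigError("window must be a positive even integer")
        unknown = set(self.site_counts) - set(SITE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown site classes: {sorted(unknown)}")
        if any(v < 0 for v in self.site_counts.values()):
            raise ConfigError("site counts must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if min(self.n_genes, self.n_uninduced, self.n_induced) <= 0:
            raise ConfigError("n_genes and replicate counts must be positive")
        if self.n_activated > self.n_genes:
            raise ConfigError("n_activated exceeds n_genes")
        if sum(self.tissue_set_sizes.values()) > self.n_genes:
            raise ConfigError("tissue sets exceed gene universe")
        if self.n_tissues < 2 or self.n_tissues > len(TISSUES):
            raise ConfigError(f"n_tissues must lie in [2, {len(TISSUES)}]")
        if self.n_activated > self.tissue_set_sizes.get("liver", self.n_genes):
            raise ConfigError("activated genes must fit in the liver tissue set")

    def noise_free(self) -> "SimConfig":
        cfg = SimConfig.from_dict(self.to_dict())
        cfg.jitter_sd = 0.0
        cfg.dropout = 0.0
        return cfg

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif_multiplicity"] = {
            tf: {cls: list(rng) for cls, rng in per.items()}
            for tf, per in self.motif_multiplicity.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "motif_multiplicity" in d:
            d["motif_multiplicity"] = {
                tf: {cls: tuple(rng) for cls, rng in per.items()}
                for tf, per in d["motif_multiplicity"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Synthetic PWMs
# ---------------------------------------------------------------------------

# Synthetic stand-in count matrices (columns x (A, C, G, T), counts of 100).
# They are NOT the curated database motifs for these factors -- only
# plausible imitations: a forkhead-like 12-mer around a TGTTT[AG]C core and a
# nuclear-receptor-like 13-mer with two GGTCA-like half sites, with total
# information content in the 10-12 bit range typical of such motifs.
_FOXA1_LIKE_COUNTS = [
    (30, 20, 20, 30),
    (60, 8, 8, 24),
    (3, 3, 2, 92),
    (3, 3, 91, 3),
    (2, 3, 3, 92),
    (2, 3, 3, 92),
    (5, 3, 2, 90),
    (85, 5, 3, 7),
    (5, 85, 5, 5),
    (10, 10, 8, 72),
    (45, 20, 12, 23),
    (25, 25, 25, 25),
]
_HNF4A_LIKE_COUNTS = [
    (20, 20, 40, 20),
    (8, 4, 84, 4),
    (4, 4, 88, 4),
    (4, 8, 8, 80),
    (8, 76, 8, 8),
    (80, 8, 8, 4),
    (76, 8, 8, 8),
    (50, 15, 20, 15),
    (8, 4, 84, 4),
    (4, 4, 88, 4),
    (4, 8, 8, 80),
    (8, 76, 8, 8),
    (76, 8, 8, 8),
]


def default_pwms(pseudocount: float = 0.1) -> Dict[str, PWM]:
    """The two synthetic factor PWMs used throughout the simulations."""
    return {
        "FOXA1": PWM.from_counts(
            "FOXA1_like_synthetic", np.asarray(_FOXA1_LIKE_COUNTS, float),
            pseudocount=pseudocount,
        ),
        "HNF4A": PWM.from_counts(
            "HNF4A_like_synthetic", np.asarray(_HNF4A_LIKE_COUNTS, float),
            pseudocount=pseudocount,
        ),
    }


# ---------------------------------------------------------------------------
# Genome and sites
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Genome:
    """I.i.d. random genome with the configured GC content."""
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for chrom, size in config.chrom_sizes.items():
        draws = rng.choice(4, size=size, p=p)
        seqs[chrom] = base_bytes[draws].tobytes().decode("ascii")
    return Genome(seqs)


@dataclass
class SitePlan:
    """Ground-truth ledger of planted sites.

    Columns: site_id, chrom, start, end, cls, n_foxa1, n_hnf4a, gene_id
    (empty string when the site is not linked to a gene).
    """

    table: pd.DataFrame

    COLUMNS = ("site_id", "chrom", "start", "end", "cls", "n_foxa1", "n_hnf4a", "gene_id")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise SimulationError(f"site plan missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def of_class(self, *classes: str) -> pd.DataFrame:
        return self.table[self.table["cls"].isin(classes)]

    def peakset(self, *classes: str) -> PeakSet:
        sub = self.of_class(*classes) if classes else self.table
        return PeakSet(
            GenomicInterval(r.chrom, r.start, r.end, name=r.site_id)
            for r in sub.itertuples(index=False)
        )

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SitePlan":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False,
                               dtype={"gene_id": str, "chrom": str}))


def _draw_multiplicity(
    config: SimConfig, tf: str, cls: str, rng: np.random.Generator
) -> int:
    lo, hi = config.motif_multiplicity.get(tf, {}).get(cls, (0, 0))
    if hi < lo:
        raise ConfigError(f"bad multiplicity range for ({tf}, {cls})")
    return int(rng.integers(lo, hi + 1))


def plant_sites(
    genome: Genome,
    config: SimConfig,
    pwms: Mapping[str, PWM],
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Genome, SitePlan]:
    """Choose disjoint 500-bp windows and write motif instances into them.

    Windows are drawn from a genome-wide grid of slots (window + spacing wide)
    without replacement, so they are disjoint by construction.  For each site
    the class-specified number of instances of each factor's motif is sampled
    from the PWM columns (or forced to consensus when
    ``config.consensus_motifs``), written at non-overlapping offsets on a
    random strand, and recorded in the ledger.
    """
    rng = rng or np.random.default_rng(config.seed)
    from .motifs import _int_scores, build_score_null  # local to avoid cycle

    detect_min: Dict[str, int] = {}
    int_tables: Dict[str, np.ndarray] = {}
    if config.min_instance_pvalue is not None and not config.consensus_motifs:
        gc = config.gc_content
        genome_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for tf, pwm in pwms.items():
            # detectability judged under the composition the scan will see
            scan_pwm = PWM(pwm.id, pwm.probs, background=genome_bg,
                           pseudocount=pwm.pseudocount)
            null = build_score_null(scan_pwm)
            detect_min[tf] = null.min_int_for_pvalue(config.min_instance_pvalue)
            int_tables[tf] = _int_scores(scan_pwm, null.granularity)

    def draw_instance(tf: str, pwm: PWM) -> str:
        if config.consensus_motifs:
            return pwm.consensus()
        if tf not in detect_min:
            return pwm.sample_instance(rng)
        ints = int_tables[tf]
        for _ in range(1000):
            inst = pwm.sample_instance(rng)
            score = sum(int(ints[i, "ACGT".index(b)]) for i, b in enumerate(inst))
            if score >= detect_min[tf]:
                return inst
        raise SimulationError(f"could not sample a detectable {tf} instance")

    window, spacing = config.window, config.site_spacing
    slot = window + spacing
    slots: List[Tuple[str, int]] = []
    for chrom, size in config.chrom_sizes.items():
        slots.extend((chrom, k * slot) for k in range(size // slot))
    n_sites = sum(config.site_counts.values())
    if n_sites > len(slots):
        raise SimulationError(
            f"cannot place {n_sites} disjoint windows; only {len(slots)} slots"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_sites, replace=False)]
    classes: List[str] = []
    for cls in SITE_CLASSES:  # fixed order, then shuffled
        classes.extend([cls] * config.site_counts.get(cls, 0))
    classes = [classes[i] for i in rng.permutation(n_sites)]

    seqs = {chrom: bytearray(genome.sequence(chrom), "ascii") for chrom in genome.chroms()}
    rows = []
    for idx, ((chrom, slot_start), cls) in enumerate(zip(chosen, classes)):
        offset_slack = spacing  # window floats inside its slot
        start = slot_start + int(rng.integers(0, offset_slack + 1))
        end = start + window
        occupied: List[Tuple[int, int]] = []
        counts = {"FOXA1": 0, "HNF4A": 0}
        for tf in ("FOXA1", "HNF4A"):
            pwm = pwms[tf]
            k = _draw_multiplicity(config, tf, cls, rng)
            for _ in range(k):
                inst = draw_instance(tf, pwm)
                if rng.integers(2):
                    inst = reverse_complement(inst)
                placed = False
                for _attempt in range(200):
                    pos = int(rng.integers(0, window - pwm.width + 1))
                    if all(pos + pwm.width <= a or pos >= b for a, b in occupied):
                        placed = True
                        break
                if not placed:
                    raise SimulationError(
                        f"could not place motif instance in site {idx} ({cls})"
                    )
                occupied.append((pos, pos + pwm.width))
                seqs[chrom][start + pos : start + pos + pwm.width] = inst.encode("ascii")
                counts[tf] += 1
        rows.append(
            {
                "site_id": f"site{idx:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "cls": cls,
                "n_foxa1": counts["FOXA1"],
                "n_hnf4a": counts["HNF4A"],
                "gene_id": "",
            }
        )
    plan = SitePlan(pd.DataFrame(rows, columns=list(SitePlan.COLUMNS)))
    new_genome = Genome({chrom: bytes(b).decode("ascii") for chrom, b in seqs.items()})
    return new_genome, plan


def generate_genes(
    plan: SitePlan,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    link_halfwidth: int = 20_000,
) -> GeneAnnotation:
    """Gene annotation with activated genes linked to co-bound sites.

    The first ``n_activated`` gene ids get TSSs within ``link_halfwidth`` of
    distinct co-bound site windows (and those sites' ledger rows record the
    gene id); remaining genes are placed uniformly at random.
    """
    rng = rng or np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    cobound = plan.of_class(*COBOUND_CLASSES)
    if len(cobound) < config.n_activated:
        raise SimulationError(
            f"need >= {config.n_activated} co-bound sites to anchor activated genes"
        )
    rows = []
    link_rows = cobound.index[: config.n_activated]
    for gid, row_idx in zip(gene_ids[: config.n_activated], link_rows):
        site = plan.table.loc[row_idx]
        mid = int(site.start) + config.window // 2
        tss = mid + int(rng.integers(-link_halfwidth, link_halfwidth + 1))
        tss = min(max(tss, 0), config.chrom_sizes[site.chrom] - 1)
        strand = "+" if rng.integers(2) else "-"
        rows.append({"id": gid, "chrom": site.chrom, "tss": tss, "strand": strand})
        plan.table.loc[row_idx, "gene_id"] = gid
    for gid in gene_ids[config.n_activated :]:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        tss = int(rng.integers(0, config.chrom_sizes[chrom]))
        strand = "+" if rng.integers(2) else "-"
        rows.append({"id": gid, "chrom": chrom, "tss": tss, "strand": strand})
    return GeneAnnotation(pd.DataFrame(rows, columns=["id", "chrom", "tss", "strand"]))


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def _site_tracks(cls: str) -> Tuple[str, ...]:
    tracks = CLASS_TRACKS[cls]
    if cls in ACCESSIBLE_CLASSES:
        return tracks + ("atac_pre", "atac_post")
    if cls == "background":
        return ()
    return tracks + ("atac_post",)  # bound inaccessible sites are opened


def generate_peaksets(
    plan: SitePlan,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Tuple[PeakSet, PeakSet]]:
    """Two noisy replicates per track implied by the site classes.

    Each site's 500-bp window becomes a peak in every track its class
    implies.  Per replicate, both boundaries receive independent Gaussian
    jitter (sd ``jitter_sd``) and the whole peak is dropped with probability
    ``dropout``.
    """
    rng = rng or np.random.default_rng(config.seed)
    members: Dict[str, list] = {t: [] for t in TRACKS}
    for row in plan.table.itertuples(index=False):
        for track in _site_tracks(row.cls):
            members[track].append(row)
    out: Dict[str, Tuple[PeakSet, PeakSet]] = {}
    for track in TRACKS:
        reps: List[List[GenomicInterval]] = [[], []]
        for row in members[track]:
            size = config.chrom_sizes[row.chrom]
            for r in range(2):
                if config.dropout > 0 and rng.random() < config.dropout:
                    continue
                if config.jitter_sd > 0:
                    ds, de = np.rint(rng.normal(0.0, config.jitter_sd, 2)).astype(int)
                else:
                    ds = de = 0
                start = max(0, int(row.start) + int(ds))
                end = min(size, int(row.end) + int(de))
                if end <= start:
                    end = min(size, start + 1)
                reps[r].append(GenomicInterval(row.chrom, start, end, name=row.site_id))
        out[track] = (
            PeakSet(reps[0], label=f"{track}_rep1"),
            PeakSet(reps[1], label=f"{track}_rep2"),
        )
    return out


# ---------------------------------------------------------------------------
# Counts and tissue table
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, means: np.ndarray, size_param: float) -> np.ndarray:
    """Vectorized NB draws with per-gene means; a zero mean yields zero counts."""
    means = np.asarray(means, dtype=float)
    p = size_param / (size_param + means)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def generate_counts(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CountMatrix, Set[str]]:
    """Negative-binomial count matrix with planted activation.

    The first ``n_activated`` genes have a silent uninduced baseline
    (``activated_base_mean`` normalized reads) and an induced mean scaled by
    ``2 ** activated_lfc``; all other genes draw a log-normal baseline around
    ``nb_mean`` shared between conditions.  Returns the counts plus the truth
    set of activated gene ids (empty when ``activated_lfc == 0``).
    """
    rng = rng or np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    n_act = config.n_activated
    base = np.empty(config.n_genes)
    base[:n_act] = config.activated_base_mean
    base[n_act:] = rng.lognormal(
        mean=np.log(config.nb_mean), sigma=config.baseline_sigma,
        size=config.n_genes - n_act,
    )
    induced_mean = base.copy()
    induced_mean[:n_act] = base[:n_act] * 2.0 ** config.activated_lfc
    samples = [f"uninduced_{i + 1}" for i in range(config.n_uninduced)]
    samples += [f"induced_{i + 1}" for i in range(config.n_induced)]
    data = {}
    for s in samples[: config.n_uninduced]:
        data[s] = _nb_draw(rng, base, config.nb_dispersion)
    for s in samples[config.n_uninduced :]:
        data[s] = _nb_draw(rng, induced_mean, config.nb_dispersion)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"))
    conditions = {s: ("uninduced" if s.startswith("uninduced") else "induced")
                  for s in samples}
    truth = set(gene_ids[:n_act]) if config.activated_lfc != 0 else set()
    return CountMatrix(counts, conditions), truth


def tissue_truth_sets(config: SimConfig) -> Dict[str, Set[str]]:
    """Disjoint planted tissue-enriched gene sets.

    The liver set contains every planted activated gene (so activation is
    genuinely liver-enriched) padded with inactive genes to its configured
    size; further sets take the next blocks of gene ids.
    """
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sets: Dict[str, Set[str]] = {}
    cursor = config.n_activated
    for tissue, size in config.tissue_set_sizes.items():
        if tissue == "liver":
            extra = size - config.n_activated
            sets[tissue] = set(gene_ids[: config.n_activated]) | set(
                gene_ids[cursor : cursor + extra]
            )
            cursor += extra
        else:
            sets[tissue] = set(gene_ids[cursor : cursor + size])
            cursor += size
    return sets


def generate_tissue_table(
    config: SimConfig,
    truth_sets: Mapping[str, Set[str]],
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Genes x tissues expression table with planted enrichment.

    Baseline values are uniform on [5, 15] (max/min ratio 3, so no baseline
    gene can satisfy a fourfold rule); each truth gene's own-tissue value is
    then set to exactly ``tissue_fold`` times its maximum other-tissue value.
    """
    rng = rng or np.random.default_rng(config.seed)
    tissues = list(TISSUES[: config.n_tissues])
    unknown = set(truth_sets) - set(tissues)
    if unknown:
        raise ConfigError(f"truth sets for unknown tissues: {sorted(unknown)}")
    seen: Set[str] = set()
    for tissue, genes in truth_sets.items():
        if seen & genes:
            raise ConfigError("tissue truth sets must be disjoint")
        seen |= genes
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    table = pd.DataFrame(
        rng.uniform(5.0, 15.0, size=(config.n_genes, len(tissues))),
        index=pd.Index(gene_ids, name="gene"),
        columns=tissues,
    )
    for tissue, genes in truth_sets.items():
        idx = table.index.isin(genes)
        others = table.loc[idx, [t for t in tissues if t != tissue]]
        table.loc[idx, tissue] = config.tissue_fold * others.max(axis=1)
    return table


# ---------------------------------------------------------------------------
# Chromatin segmentation
# ---------------------------------------------------------------------------

_STATE_PREFS = {
    "FP": (("Promoter", 0.45), ("Enhancer", 0.45), ("Heterochrom", 0.05), ("Repressed", 0.05)),
    "HP": (("Promoter", 0.45), ("Enhancer", 0.45), ("Heterochrom", 0.05), ("Repressed", 0.05)),
    "BOTH": (("Promoter", 0.45), ("Enhancer", 0.45), ("Heterochrom", 0.05), ("Repressed", 0.05)),
    "CB": (("Promoter", 0.1), ("Enhancer", 0.2), ("Heterochrom", 0.4), ("Repressed", 0.3)),
}
_DEFAULT_PREF = (("Enhancer", 0.4), ("Quies", 0.6))


def generate_chromhmm(
    plan: SitePlan,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PeakSet:
    """A toy chromatin-state segmentation tiling the genome without gaps.

    Site windows receive a state drawn from a class-dependent preference
    (cooperative sites lean heterochromatic/repressed, pioneered sites lean
    promoter/enhancer); everything between sites is quiescent.
    """
    rng = rng or np.random.default_rng(config.seed)
    segs: List[GenomicInterval] = []
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {c: [] for c in config.chrom_sizes}
    for row in plan.table.itertuples(index=False):
        prefs = _STATE_PREFS.get(row.cls, _DEFAULT_PREF)
        states = [s for s, _ in prefs]
        probs = np.array([p for _, p in prefs])
        state = states[int(rng.choice(len(states), p=probs / probs.sum()))]
        by_chrom[row.chrom].append((int(row.start), int(row.end), state))
    for chrom, size in config.chrom_sizes.items():
        cursor = 0
        for start, end, state in sorted(by_chrom[chrom]):
            if start > cursor:
                segs.append(GenomicInterval(chrom, cursor, start, name="Quies"))
            segs.append(GenomicInterval(chrom, start, end, name=state))
            cursor = end
        if cursor < size:
            segs.append(GenomicInterval(chrom, cursor, size, name="Quies"))
    return PeakSet(segs, label="chromhmm")


# ---------------------------------------------------------------------------
# End-to-end simulation
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    """Everything one synthetic run produces, in memory."""

    config: SimConfig
    genome: Genome
    plan: SitePlan
    pwms: Dict[str, PWM]
    peaksets: Dict[str, Tuple[PeakSet, PeakSet]]
    genes: GeneAnnotation
    counts: CountMatrix
    activated_truth: Set[str]
    tissue_sets: Dict[str, Set[str]]
    tissue_table: pd.DataFrame
    chromhmm: PeakSet


def simulate_dataset(
    config: SimConfig, pwms: Optional[Mapping[str, PWM]] = None
) -> SimDataset:
    """Run the whole generator in the documented draw order.

    Order: genome bases, site placement and motif planting, gene placement,
    peak replicas, counts, tissue table, chromatin segmentation -- all from a
    single generator seeded with ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pwms = dict(pwms) if pwms is not None else default_pwms()
    genome = generate_genome(config, rng)
    genome, plan = plant_sites(genome, config, pwms, rng)
    genes = generate_genes(plan, config, rng)
    peaksets = generate_peaksets(plan, config, rng)
    counts, truth = generate_counts(config, rng)
    tsets = tissue_truth_sets(config)
    tissue_table = generate_tissue_table(config, tsets, rng)
    chromhmm = generate_chromhmm(plan, config, rng)
    return SimDataset(
        config=config,
        genome=genome,
        plan=plan,
        pwms=pwms,
        peaksets=peaksets,
        genes=genes,
        counts=counts,
        activated_truth=truth,
        tissue_sets=tsets,
        tissue_table=tissue_table,
        chromhmm=chromhmm,
    )
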