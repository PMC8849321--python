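"""Expression analysis: normalization, activation calls, tissue enrichment.

The differential stage is intentionally transparent: median-of-ratios size
factors (the DESeq convention), per-condition means of normalized counts, and
a pseudocounted log2 fold change.  Shrinkage-based differential models are
out of scope here; an externally produced per-gene table with the same
columns can be supplied wherever a :func:`differential_table` result is
accepted.

Activation calls follow two rules: a gene is *upregulated* if its log2 fold
change is at least ``lfc_min`` (default 1), and *activated* if it is
upregulated AND essentially silent before induction, i.e. fewer than
``base_max`` (default 50) normalized reads in the uninduced condition.  When
an adjusted p-value column is present, calls additionally require
``padj <= 0.05``.

Tissue-enriched gene sets use the fourfold rule: a gene belongs to a tissue's
set iff its expression there is at least ``fold`` (default 4) times its
maximum expression in any other tissue.  Enrichment of an activated gene set
in a tissue set is scored with the upper-tail (cumulative) hypergeometric
probability, computed in log space so that genome-scale arguments do not
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, UsageError

__all__ = [
    "CountMatrix",
    "TissueGeneSet",
    "size_factors",
    "differential_table",
    "call_activated",
    "call_upregulated",
    "tissue_enriched_genes",
    "hypergeom_enrichment",
    "enrichment_report",
]

MIN_TOTAL_READS = 10  # genes below this raw total are dropped before analysis


@dataclass
class CountMatrix:
    """Gene x sample raw counts plus a sample -> condition mapping."""

    counts: pd.DataFrame  # index: gene ids; columns: sample names
    conditions: Dict[str, str]  # sample -> {"uninduced", "induced"}

    def __post_init__(self) -> None:
        extra = set(self.counts.columns) - set(self.conditions)
        if extra:
            raise UsageError(f"samples without condition label: {sorted(extra)}")
        values = set(self.conditions.values())
        if not values <= {"uninduced", "induced"}:
            raise UsageError(f"unknown condition labels: {values}")
        for cond in ("uninduced", "induced"):
            if not any(self.conditions[s] == cond for s in self.counts.columns):
                raise UsageError(f"no sample with condition {cond!r}")
        if (self.counts.values < 0).any():
            raise UsageError("counts must be non-negative")

    def samples(self, condition: str) -> List[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [f"{s}:{self.conditions[s]}" for s in out.columns]
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        conditions = {}
        names = []
        for col in df.columns:
            if ":" not in col:
                raise UsageError(f"{path}: column {col!r} lacks ':condition' suffix")
            name, cond = col.rsplit(":", 1)
            names.append(name)
            conditions[name] = cond
        df.columns = names
        return cls(df, conditions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with a positive count in every sample, form the ratio of each
    sample's count to the gene's geometric mean across samples; the sample's
    factor is the median of those ratios.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in every sample")
    sub = mat[positive]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def differential_table(cm: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene normalized condition means and log2 fold change.

    Genes with fewer than 10 raw reads in total are filtered out before
    normalization.  Returns a frame indexed by gene id with columns
    ``uninduced_mean``, ``induced_mean``, ``log2fc``.
    """
    keep = cm.counts.sum(axis=1) >= MIN_TOTAL_READS
    counts = cm.counts.loc[keep]
    if counts.empty:
        raise UsageError("no gene passes the minimum-reads filter")
    factors = size_factors(counts)
    norm = counts / factors
    unind = norm[cm.samples("uninduced")].mean(axis=1)
    ind = norm[cm.samples("induced")].mean(axis=1)
    log2fc = np.log2((ind + pseudocount) / (unind + pseudocount))
    return pd.DataFrame(
        {"uninduced_mean": unind, "induced_mean": ind, "log2fc": log2fc}
    )


def call_activated(
    diff: pd.DataFrame,
    lfc_min: float = 1.0,
    base_max: float = 50.0,
    padj_max: float = 0.05,
) -> Set[str]:
    """Genes activated from a silent baseline.

    A gene qualifies iff ``log2fc >= lfc_min`` and ``uninduced_mean <
    base_max``; when the table carries a ``padj`` column, additionally
    ``padj <= padj_max``.
    """
    mask = (diff["log2fc"] >= lfc_min) & (diff["uninduced_mean"] < base_max)
    if "padj" in diff.columns:
        mask &= diff["padj"].notna() & (diff["padj"] <= padj_max)
    return set(diff.index[mask])


def call_upregulated(diff: pd.DataFrame, lfc_min: float = 1.0) -> Set[str]:
    """Genes with log2 fold change at least ``lfc_min``."""
    return set(diff.index[diff["log2fc"] >= lfc_min])


@dataclass
class TissueGeneSet:
    tissue: str
    genes: Set[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.genes) > self.universe_size:
            raise UsageError("tissue gene set larger than its universe")


def tissue_enriched_genes(
    table: pd.DataFrame, tissue: str, fold: float = 4.0
) -> TissueGeneSet:
    """Genes at least ``fold`` times higher expressed in ``tissue`` than in
    any other tissue.

    ``table`` is genes x tissues.  A gene with positive expression in the
    tissue and zero everywhere else counts as enriched; an all-zero gene does
    not.
    """
    if tissue not in table.columns:
        raise UsageError(f"tissue {tissue!r} not in table")
    if table.shape[1] < 2:
        raise UsageError("need at least 2 tissues")
    own = table[tissue]
    other_max = table.drop(columns=[tissue]).max(axis=1)
    enriched = (own > 0) & (own >= fold * other_max)
    return TissueGeneSet(tissue, set(table.index[enriched]), universe_size=len(table))


def hypergeom_enrichment(
    k_obs: int, set_size: int, n_activated: int, universe: int
) -> Tuple[float, float]:
    """Expected overlap and upper-tail hypergeometric p-value.

    Drawing ``n_activated`` genes from a universe of ``universe`` containing
    ``set_size`` tissue-set genes, returns ``(expected, P(X >= k_obs))`` with
    the tail computed in log space.
    """
    if not (0 <= set_size <= universe and 0 <= n_activated <= universe):
        raise UsageError("need set_size, n_activated in [0, universe]")
    if not (0 <= k_obs <= min(set_size, n_activated)):
        raise UsageError("k_obs out of range")
    expected = n_activated * set_size / universe if universe else 0.0
    if k_obs == 0:
        return expected, 1.0
    logp = stats.hypergeom.logsf(k_obs - 1, universe, set_size, n_activated)
    return expected, float(np.exp(logp))


def enrichment_report(
    activated: Set[str],
    tissue_sets: Sequence[TissueGeneSet],
    universe_genes: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of an activated gene set in each tissue set.

    The universe is the set of testable genes (those that survived the
    minimum-reads filter); tissue sets and the activated set are intersected
    with it before testing.  Returns columns tissue, K, n, N, observed,
    expected, pvalue.
    """
    universe = set(universe_genes)
    act = activated & universe
    rows = []
    for ts in tissue_sets:
        genes = ts.genes & universe
        k = len(act & genes)
        expected, pvalue = hypergeom_enrichment(k, len(genes), len(act), len(universe))
        rows.append(
            {
                "tissue": ts.tissue,
                "K": len(genes),
                "n": len(act),
                "N": len(universe),
                "observed": k,
                "expected": expected,
                "pvalue": pvalue,
            }
        )
    return pd.DataFrame(rows)
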