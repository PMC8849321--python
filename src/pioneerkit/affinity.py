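"""The affinity model: can motif content alone predict binding?

The working hypothesis is that 'pioneer activity' is not a categorical
property of special factors but a function of the affinity between a factor
and a stretch of DNA -- operationalized here as the aggregate motif content
of the 500-bp window around a site.  A bare threshold on that score is used
as a classifier, and its quality is summarized by the ROC curve obtained by
sweeping the threshold (score >= t => predicted bound), with the area under
the curve computed by the trapezoid rule.  With ties handled as single steps
this AUC equals the Mann-Whitney U statistic normalized by
``n_pos * n_neg`` -- the probability that a random positive outscores a
random negative, counting ties as one half.

Group comparisons (e.g. motif count at pioneered vs cooperatively bound
sites) are reported as boxplot-style five-number summaries; no hypothesis
test is attached, as the comparisons of interest are distributional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import UsageError
from .genome import Genome
from .intervals import (
    GenomicInterval,
    PeakSet,
    midpoint_window,
    sample_random_inaccessible,
)
from .motifs import PWM, aggregate_affinity_score

__all__ = [
    "ROCResult",
    "GroupSummary",
    "roc_curve",
    "compare_groups",
    "binding_prediction_experiment",
    "window_scores",
]


@dataclass
class ROCResult:
    """Threshold sweep of a score-threshold classifier."""

    thresholds: np.ndarray  # descending; first entry +inf (nothing predicted)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> ROCResult:
    """ROC of the classifier ``score >= threshold -> positive``.

    Thresholds sweep the union of observed scores in descending order (tied
    scores form a single step), preceded by +inf where nothing is called
    positive.  AUC is the trapezoidal area under (fpr, tpr).
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UsageError("roc_curve requires at least one score on each side")
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count(x >= t) = n - searchsorted_left(t)
    tp = pos.size - np.searchsorted(pos_sorted, thr, side="left")
    fp = neg.size - np.searchsorted(neg_sorted, thr, side="left")
    tpr = np.concatenate([[0.0], tp / pos.size])
    fpr = np.concatenate([[0.0], fp / neg.size])
    thresholds = np.concatenate([[np.inf], thr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, fpr, tpr, auc, int(pos.size), int(neg.size))


@dataclass
class GroupSummary:
    """Boxplot-style summary: quartiles plus 1.5 x IQR whisker bounds."""

    label: str
    n: int
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def compare_groups(groups: Mapping[str, Sequence[float]]) -> List[GroupSummary]:
    """Five-number summaries for each named score group.

    Whiskers extend to the most extreme data point within 1.5 x IQR of the
    box, the usual boxplot convention.
    """
    out = []
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise UsageError(f"group {label!r} is empty")
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        in_low = arr[arr >= q1 - 1.5 * iqr]
        in_high = arr[arr <= q3 + 1.5 * iqr]
        out.append(
            GroupSummary(
                label=label,
                n=int(arr.size),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                whisker_low=float(in_low.min()),
                whisker_high=float(in_high.max()),
            )
        )
    return out


def window_scores(
    genome: Genome,
    pwms: Sequence[PWM],
    sites: Sequence[GenomicInterval],
    window: int = 500,
    mode: str = "sum",
) -> np.ndarray:
    """Aggregate affinity score of the fixed-width window around each site."""
    scores = np.empty(len(sites))
    for i, site in enumerate(sites):
        win, _ = midpoint_window(site, width=window,
                                 chrom_size=genome.sizes[site.chrom])
        scores[i] = aggregate_affinity_score(pwms, genome, win, mode=mode)
    return scores


def binding_prediction_experiment(
    genome: Genome,
    pwms: Mapping[str, PWM],
    single_sites: Mapping[str, Tuple[PeakSet, np.ndarray]],
    atac_pre: PeakSet,
    seed: int,
    cobound: Optional[PeakSet] = None,
    cobind_labels: Optional[Sequence[str]] = None,
    window: int = 500,
    mode: str = "sum",
) -> Dict[str, ROCResult]:
    """The suite of motif-content-predicts-binding comparisons.

    ``single_sites`` maps each factor name to its (replicate-merged) binding
    peaks plus a boolean accessibility array.  For each factor the experiment
    scores 500-bp midpoint windows with that factor's PWM and builds:

    * ``{tf}_accessible_vs_random``   -- accessible bound sites vs random
      windows;
    * ``{tf}_inaccessible_vs_random`` -- inaccessible bound sites vs
      length-matched random inaccessible windows;

    and, when co-bound sites with class labels are supplied, using the
    combined two-PWM score for co-binding and the single relevant PWM for the
    pioneered-vs-cooperative contrasts:

    * ``cobound_inaccessible_vs_random``;
    * ``FP_vs_CB`` (first factor's PWM) and ``HP_vs_CB`` (second factor's).

    Random negatives are drawn 1:1 with the positives, avoiding accessible
    regions and every assayed binding site, so they represent untouched
    background sequence.  Comparisons with an empty side are skipped.
    """
    rng = np.random.default_rng(seed)
    tf_names = list(pwms)
    avoid_ivs: List[GenomicInterval] = list(atac_pre)
    for ps, _ in single_sites.values():
        avoid_ivs.extend(ps)
    if cobound is not None:
        avoid_ivs.extend(cobound)
    avoid = PeakSet(avoid_ivs)

    def negatives(n: int) -> List[GenomicInterval]:
        return list(sample_random_inaccessible(genome, avoid, n, window, rng))

    results: Dict[str, ROCResult] = {}
    for tf in tf_names:
        if tf not in single_sites:
            continue
        peaks, accessible = single_sites[tf]
        accessible = np.asarray(accessible, dtype=bool)
        if len(accessible) != len(peaks):
            raise UsageError(f"{tf}: accessibility array length mismatch")
        for flag, name in ((True, "accessible"), (False, "inaccessible")):
            sites = [iv for iv, a in zip(peaks, accessible) if a == flag]
            if not sites:
                continue
            pos = window_scores(genome, [pwms[tf]], sites, window=window, mode=mode)
            neg = window_scores(
                genome, [pwms[tf]], negatives(len(sites)), window=window, mode=mode
            )
            results[f"{tf}_{name}_vs_random"] = roc_curve(pos, neg)

    if cobound is not None and cobind_labels is not None and len(cobound):
        co_acc = np.array([atac_pre.overlap_interval(iv) for iv in cobound])
        inacc = [iv for iv, a in zip(cobound, co_acc) if not a]
        if inacc:
            both = [pwms[tf] for tf in tf_names]
            pos = window_scores(genome, both, inacc, window=window, mode=mode)
            neg = window_scores(genome, both, negatives(len(inacc)),
                                window=window, mode=mode)
            results["cobound_inaccessible_vs_random"] = roc_curve(pos, neg)
        by_class: Dict[str, List[GenomicInterval]] = {}
        for iv, lab in zip(cobound, cobind_labels):
            by_class.setdefault(lab, []).append(iv)
        cb = by_class.get("CB", [])
        if cb:
            for cls, tf in (("FP", tf_names[0]), ("HP", tf_names[1])):
                sites = by_class.get(cls, [])
                if not sites:
                    continue
                pos = window_scores(genome, [pwms[tf]], sites, window=window, mode=mode)
                neg = window_scores(genome, [pwms[tf]], cb, window=window, mode=mode)
                results[f"{cls}_vs_CB"] = roc_curve(pos, neg)
    return results
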