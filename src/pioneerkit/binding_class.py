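"""Binding-site classification by prior accessibility and co-binding mode.

A bound site is *accessible* iff it overlaps at least one peak of the
uninduced (pre-induction) accessibility track, else *inaccessible*.  An
inaccessible bound site is *opened* iff it overlaps an induced accessibility
peak -- opening is defined only for sites that started closed.

Co-bound sites are loci where the two factors' double-expression binding
tracks overlap; each maximal transitively-overlapping cluster containing at
least one peak from each factor yields one co-bound site (union span).  The
four-way co-binding taxonomy then asks which factors bound the locus when
expressed alone:

* ``FP``   -- overlaps a FOXA1 single-expression peak only (FOXA1 pioneered);
* ``HP``   -- overlaps an HNF4A single-expression peak only (HNF4A pioneered);
* ``BOTH`` -- overlaps single-expression peaks of both factors;
* ``CB``   -- overlaps neither: binding appears only on co-expression
  (cooperatively bound).

Chromatin-state summaries assign each site to the segmentation state with the
largest base-pair overlap (ties broken toward the leftmost-starting segment)
and report per-class state fractions.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .intervals import GenomicInterval, PeakSet, _dual_clusters

__all__ = [
    "COBIND_CLASSES",
    "classify_accessibility",
    "classify_opened",
    "cobound_sites",
    "classify_cobinding",
    "chromhmm_fractions",
    "site_classification_table",
]

COBIND_CLASSES = ("FP", "HP", "BOTH", "CB")
UNASSIGNED_STATE = "Unassigned"


def classify_accessibility(binding: PeakSet, atac_pre: PeakSet) -> np.ndarray:
    """Boolean array, one entry per binding site: overlapped a pre-induction
    accessibility peak (accessible) or not (inaccessible)."""
    return np.array([atac_pre.overlap_interval(iv) for iv in binding], dtype=bool)


def classify_opened(
    binding: PeakSet, atac_pre: PeakSet, atac_post: PeakSet
) -> np.ndarray:
    """Boolean array: site was inaccessible before induction AND overlaps an
    induced accessibility peak.  Already-accessible sites are never 'opened'."""
    accessible = classify_accessibility(binding, atac_pre)
    post = np.array([atac_post.overlap_interval(iv) for iv in binding], dtype=bool)
    return ~accessible & post


def cobound_sites(foxa1_dbl: PeakSet, hnf4a_dbl: PeakSet) -> PeakSet:
    """Co-bound loci from the two double-expression binding tracks.

    One site per maximal mutually-overlapping cluster containing at least one
    peak from each factor; coordinates are the cluster's union span.
    """
    out = [
        GenomicInterval(chrom, start, end)
        for chrom, start, end, ha, hb in _dual_clusters(foxa1_dbl, hnf4a_dbl)
        if ha and hb
    ]
    return PeakSet(out, label="cobound")


def classify_cobinding(
    cobound: PeakSet, foxa1_single: PeakSet, hnf4a_single: PeakSet
) -> List[str]:
    """Assign each co-bound site exactly one of FP / HP / BOTH / CB."""
    labels = []
    for iv in cobound:
        f = foxa1_single.overlap_interval(iv)
        h = hnf4a_single.overlap_interval(iv)
        if f and h:
            labels.append("BOTH")
        elif f:
            labels.append("FP")
        elif h:
            labels.append("HP")
        else:
            labels.append("CB")
    return labels


def _validate_segments(segments: PeakSet) -> None:
    prev = None
    for iv in segments:
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
            raise UsageError(
                f"overlapping segments {prev.chrom}:{prev.start}-{prev.end} and "
                f"{iv.chrom}:{iv.start}-{iv.end}"
            )
        prev = iv


def assign_chromhmm_state(site: GenomicInterval, segments: PeakSet) -> str:
    """State with maximal bp overlap; ties go to the leftmost-starting
    segment; no overlap at all yields the 'Unassigned' category."""
    best_state, best_bp = UNASSIGNED_STATE, 0
    for seg in segments.query(site.chrom, site.start, site.end):
        bp = min(site.end, seg.end) - max(site.start, seg.start)
        if bp > best_bp:  # strictly greater: first (leftmost) segment wins ties
            best_state, best_bp = seg.name or UNASSIGNED_STATE, bp
    return best_state


def chromhmm_fractions(
    sites_by_class: Mapping[str, PeakSet], segments: PeakSet
) -> pd.DataFrame:
    """Fraction of each site class falling in each chromatin state.

    ``segments`` must be non-overlapping (a segmentation).  Rows are classes,
    columns states (plus 'Unassigned'); each row sums to 1 for non-empty
    classes.
    """
    _validate_segments(segments)
    counts: Dict[str, Dict[str, int]] = {}
    states = set()
    for cls, sites in sites_by_class.items():
        c: Dict[str, int] = {}
        for iv in sites:
            state = assign_chromhmm_state(iv, segments)
            c[state] = c.get(state, 0) + 1
            states.add(state)
        counts[cls] = c
    cols = sorted(states)
    rows = {}
    for cls, c in counts.items():
        total = sum(c.values())
        rows[cls] = [c.get(s, 0) / total if total else 0.0 for s in cols]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def site_classification_table(
    binding: PeakSet,
    atac_pre: PeakSet,
    atac_post: PeakSet,
    cobind_labels: Sequence[str] = (),
    segments: PeakSet = None,
) -> pd.DataFrame:
    """Per-site table: coordinates, accessibility, opened flag, optional
    co-binding class and chromatin state."""
    accessible = classify_accessibility(binding, atac_pre)
    opened = classify_opened(binding, atac_pre, atac_post)
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in binding],
            "start": [iv.start for iv in binding],
            "end": [iv.end for iv in binding],
            "accessible": accessible,
            "opened": opened,
        }
    )
    if len(cobind_labels):
        if len(cobind_labels) != len(binding):
            raise UsageError("cobind_labels length != number of sites")
        df["cobind_class"] = list(cobind_labels)
    if segments is not None:
        df["chromhmm_state"] = [assign_chromhmm_state(iv, segments) for iv in binding]
    return df
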