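"""Genomic interval algebra: the coordinate backbone of the pipeline.

All coordinates are 0-based half-open ``[start, end)``, the BED convention.
Two intervals overlap iff they share at least one base, i.e. same chromosome
and ``a.start < b.end and b.start < a.end``.  Replicate peak merging keeps only
clusters of transitively overlapping peaks that are supported by *both*
replicates, emitting the union span of each cluster -- a deliberately simple
stand-in for reproducibility filtering of peak calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, SamplingError, UsageError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "overlaps",
    "merge_replicates",
    "attribute_to_genes",
    "midpoint_window",
    "sample_random_inaccessible",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise UsageError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise UsageError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class _ChromIndex:
    """Sorted per-chromosome arrays with a running-max end for fast queries."""

    __slots__ = ("starts", "ends", "order", "maxend")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, order: np.ndarray):
        self.starts = starts
        self.ends = ends
        self.order = order
        self.maxend = np.maximum.accumulate(ends)


class PeakSet:
    """An ordered, indexed collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``.  Existence queries
    are O(log n) via per-chromosome sorted starts plus a running maximum of
    ends; enumeration of overlapping intervals scans only candidates with
    ``start < query_end``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._intervals: Tuple[GenomicInterval, ...] = tuple(ivs)
        self.label = label
        self._index: Dict[str, _ChromIndex] = {}
        by_chrom: Dict[str, List[int]] = {}
        for i, iv in enumerate(self._intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            order = np.asarray(idx, dtype=np.int64)
            starts = np.asarray([self._intervals[i].start for i in idx], dtype=np.int64)
            ends = np.asarray([self._intervals[i].end for i in idx], dtype=np.int64)
            self._index[chrom] = _ChromIndex(starts, ends, order)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<PeakSet n={len(self)}{lab}>"

    @property
    def intervals(self) -> Tuple[GenomicInterval, ...]:
        return self._intervals

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self._index)

    # -- queries ------------------------------------------------------------
    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        """True iff any stored interval overlaps ``chrom:[start, end)``."""
        ci = self._index.get(chrom)
        if ci is None:
            return False
        hi = int(np.searchsorted(ci.starts, end, side="left"))
        if hi == 0:
            return False
        return bool(ci.maxend[hi - 1] > start)

    def query(self, chrom: str, start: int, end: int) -> List[GenomicInterval]:
        """All stored intervals overlapping ``chrom:[start, end)``, in order."""
        ci = self._index.get(chrom)
        if ci is None:
            return []
        hi = int(np.searchsorted(ci.starts, end, side="left"))
        out = []
        for k in range(hi):
            if ci.ends[k] > start:
                out.append(self._intervals[int(ci.order[k])])
        return out

    def overlap_interval(self, iv: GenomicInterval) -> bool:
        return self.overlaps_any(iv.chrom, iv.start, iv.end)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path, label: str = "") -> PeakSet:
    """Read a BED3/BED6 file (tab-separated, no header) into a :class:`PeakSet`.

    Lines with ``end <= start`` or non-integer coordinates raise
    :class:`~pioneerkit.errors.ParseError` carrying the 1-based line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) "
                    "(need 0 <= start < end)"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else None
            intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return PeakSet(intervals, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED (3, 4 or 6 columns depending on content)."""
    has_name = any(iv.name is not None for iv in peaks)
    has_strand = any(iv.strand is not None for iv in peaks)
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_strand:
                cols.append(iv.name if iv.name is not None else ".")
            if has_strand:
                cols.extend(["0", iv.strand if iv.strand is not None else "."])
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Replicate merging / dual-source clustering
# ---------------------------------------------------------------------------

def _dual_clusters(
    a: PeakSet, b: PeakSet
) -> List[Tuple[str, int, int, bool, bool]]:
    """Sweep both peak lists jointly, emitting maximal transitively-overlapping
    clusters as ``(chrom, start, end, has_a, has_b)``."""
    events = [(iv.chrom, iv.start, iv.end, 0) for iv in a]
    events += [(iv.chrom, iv.start, iv.end, 1) for iv in b]
    events.sort()
    clusters = []
    cur = None  # [chrom, start, end, has_a, has_b]
    for chrom, start, end, src in events:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3 + src] = True
        else:
            if cur is not None:
                clusters.append(tuple(cur))
            cur = [chrom, start, end, src == 0, src == 1]
    if cur is not None:
        clusters.append(tuple(cur))
    return clusters


def merge_replicates(rep1: PeakSet, rep2: PeakSet, label: str = "") -> PeakSet:
    """Reproducible peaks supported by both replicates.

    Each maximal group of mutually (transitively) overlapping peaks drawn from
    the union of the two replicates that contains at least one peak from EACH
    replicate yields one output interval: the union span of the group.  Peaks
    supported by a single replicate are dropped.
    """
    out = [
        GenomicInterval(chrom, start, end)
        for chrom, start, end, ha, hb in _dual_clusters(rep1, rep2)
        if ha and hb
    ]
    return PeakSet(out, label=label or rep1.label)


# ---------------------------------------------------------------------------
# Gene annotation and attribution
# ---------------------------------------------------------------------------

class GeneAnnotation:
    """Per-gene TSS annotation: columns ``id, chrom, tss, strand``."""

    COLUMNS = ("id", "chrom", "tss", "strand")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise UsageError(f"gene annotation missing columns: {sorted(missing)}")
        if table["id"].duplicated().any():
            raise UsageError("gene ids must be unique")
        if (table["tss"] < 0).any():
            raise UsageError("TSS coordinates must be >= 0")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> List[str]:
        return list(self.table["id"])

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def attribute_to_genes(
    peaks: PeakSet, genes: GeneAnnotation, half_window: int
) -> Dict[str, PeakSet]:
    """Attribute peaks to every gene whose TSS window they overlap.

    A peak is attributed to a gene iff it overlaps
    ``[tss - half_window, tss + half_window)`` (strand-independent; a peak may
    be attributed to several genes).  Genes with no attributed peak are
    omitted from the result.
    """
    if half_window <= 0:
        raise UsageError("half_window must be positive")
    out: Dict[str, PeakSet] = {}
    for row in genes.table.itertuples(index=False):
        lo = max(0, int(row.tss) - half_window)
        hi = int(row.tss) + half_window
        if hi <= 0:
            continue
        hits = peaks.query(row.chrom, lo, hi)
        if hits:
            out[row.id] = PeakSet(hits, label=peaks.label)
    return out


# ---------------------------------------------------------------------------
# Window construction and random sampling
# ---------------------------------------------------------------------------

def midpoint_window(
    site: GenomicInterval,
    width: int = 500,
    chrom_size: Optional[int] = None,
) -> Tuple[GenomicInterval, bool]:
    """Fixed-width window centred on the site midpoint.

    ``mid = start + floor(len / 2)``; the window is ``[mid - width/2,
    mid + width/2)``.  When a chromosome size is supplied and the window would
    extend past either boundary it is clipped; the second return value flags
    whether clipping occurred.
    """
    if width <= 0 or width % 2:
        raise UsageError("window width must be a positive even integer")
    mid = site.midpoint
    lo, hi = mid - width // 2, mid + width // 2
    clipped = False
    if lo < 0:
        lo, clipped = 0, True
    if chrom_size is not None and hi > chrom_size:
        hi, clipped = chrom_size, True
    return GenomicInterval(site.chrom, lo, hi, name=site.name), clipped


_NON_ACGT_MAX_FRACTION = 0.1


def sample_random_inaccessible(
    genome,
    accessible: PeakSet,
    n: int,
    length: int,
    seed,
    max_attempts_per_draw: int = 1000,
) -> PeakSet:
    """Draw ``n`` random length-matched windows avoiding accessible regions.

    Start positions are uniform over the genome; a draw is accepted iff the
    window fits in its chromosome, overlaps no interval in ``accessible`` and
    contains < 10% non-ACGT bases.  Deterministic given ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = [c for c, size in genome.sizes.items() if size >= length]
    if not chroms:
        raise SamplingError("no chromosome long enough for requested length")
    weights = np.asarray([genome.sizes[c] - length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    out: List[GenomicInterval] = []
    budget = n * max_attempts_per_draw
    attempts = 0
    while len(out) < n:
        if attempts >= budget:
            raise SamplingError(
                f"rejection budget exhausted after {attempts} attempts; "
                f"placed {len(out)} of {n} windows"
            )
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, genome.sizes[chrom] - length + 1))
        end = start + length
        if accessible.overlaps_any(chrom, start, end):
            continue
        seq = genome.fetch(chrom, start, end)
        bad = sum(1 for b in seq if b not in "ACGT")
        if bad / length >= _NON_ACGT_MAX_FRACTION:
            continue
        out.append(GenomicInterval(chrom, start, end))
    return PeakSet(out, label="random_inaccessible")
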