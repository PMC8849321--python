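"""PWM scoring with an exact, calibrated score null.

A position weight matrix (PWM) assigns each window of its width a log-odds
score in bits, ``sum_i log2(P_motif(base_i) / P_background(base_i))``.  To
attach p-values to scores without resorting to sampling, per-position scores
are integerized on a fixed grid (``granularity`` bins per bit) and the exact
probability mass function of the integerized window score under the
background model is obtained by convolving the independent per-position score
distributions.  This is the standard dynamic-programming construction used by
FIMO-class motif scanners; p-values are upper tails of that pmf.

Bases with motif probability zero (possible at pseudocount 0) carry a score of
minus infinity; the mass of windows containing any such base is tracked
separately and such windows have p-value 1.

Scanning slides the PWM over both strands (the minus strand is scored on the
reverse complement), skips windows containing non-ACGT characters, and keeps
every hit at or below the p-value threshold -- overlapping hits and
two-strand hits at the same offset included.

The aggregate affinity score of a window sums positive log-odds contributions
over all offsets, both strands and (optionally) several PWMs:
``S = sum max(0, score)``.  It is a smooth proxy for total motif content that
lets weak partial matches contribute, and is monotone in the number of motif
instances present.  An alternative aggregate simply counts hits under a
relaxed p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParseError, UsageError
from .genome import Genome, reverse_complement
from .intervals import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreNull",
    "read_jaspar",
    "write_jaspar",
    "score_window",
    "build_score_null",
    "scan_sequence",
    "motif_count",
    "aggregate_affinity_score",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# uint8 -> base index lookup; 4 marks any non-ACGT byte
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# int64 sentinel standing for a -inf per-position score; any window sum that
# includes at least one sentinel stays far below every attainable finite sum
_NEG_INF_INT = -(2**40)
_NEG_INF_CUTOFF = -(2**39)

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1000
DEFAULT_P_THRESH = 1e-3


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 base indices (4 = non-ACGT)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T).

    ``probs`` has shape (width, 4) with rows summing to 1; ``background`` is
    the null base composition used for log-odds scores and p-values.
    """

    id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise UsageError("PWM probs must have shape (width >= 1, 4)")
        if np.any(self.probs < 0) or np.any(self.background < 0):
            raise UsageError("PWM probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise UsageError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise UsageError("PWM background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @classmethod
    def from_counts(
        cls,
        id: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: Optional[np.ndarray] = None,
    ) -> "PWM":
        """Normalize a (width, 4) count matrix with a flat per-cell pseudocount:
        ``P = (count + pc) / (column_total + 4 pc)``."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise UsageError("count matrix must have shape (width, 4)")
        if np.any(counts < 0):
            raise ParseError("negative entries in count matrix")
        if pseudocount < 0:
            raise UsageError("pseudocount must be non-negative")
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(id=id, probs=probs, background=bg, pseudocount=pseudocount)

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds vs background; -inf where the motif
        probability is exactly zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)[None, :]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def sample_instance(self, rng: np.random.Generator) -> str:
        """Draw one motif instance, sampling each column independently."""
        return "".join(
            BASES[rng.choice(4, p=self.probs[i])] for i in range(self.width)
        )


# ---------------------------------------------------------------------------
# JASPAR PFM I/O
# ---------------------------------------------------------------------------

def read_jaspar(
    path,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Optional[np.ndarray] = None,
) -> PWM:
    """Read one motif in JASPAR PFM text format.

    Expected layout: a ``>`` header line followed by four rows (A, C, G, T) of
    counts or frequencies, with or without the bracketed ``A [ ... ]`` style.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty JASPAR file")
    if lines[0].startswith(">"):
        motif_id = lines[0][1:].split()[0]
        lines = lines[1:]
    else:
        motif_id = "motif"
    if len(lines) < 4:
        raise ParseError(f"{path}: expected 4 base rows, found {len(lines)}")
    rows = []
    for base, line in zip(BASES, lines[:4]):
        body = line
        if body[:1].upper() in ("A", "C", "G", "T"):
            body = body[1:]
        body = body.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise ParseError(f"{path}: unparseable row for base {base}") from exc
        if any(v < 0 for v in values):
            raise ParseError(f"{path}: negative count for base {base}")
        rows.append(values)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged rows (widths {sorted(widths)})")
    counts = np.asarray(rows, dtype=float).T  # -> (width, 4)
    return PWM.from_counts(motif_id, counts, pseudocount=pseudocount, background=background)


def write_jaspar(pwm: PWM, path, scale: float = 1.0) -> None:
    """Write the PWM's probabilities (times ``scale``) in JASPAR PFM format."""
    mat = pwm.probs.T * scale
    with open(path, "w") as fh:
        fh.write(f">{pwm.id}\n")
        for base, row in zip(BASES, mat):
            body = " ".join(format(v, ".6f") for v in row)
            fh.write(f"{base} [ {body} ]\n")


# ---------------------------------------------------------------------------
# Scoring and the exact null
# ---------------------------------------------------------------------------

def score_window(pwm: PWM, seq: str) -> float:
    """Log-odds score (bits) of a sequence exactly one motif width long."""
    if len(seq) != pwm.width:
        raise UsageError(f"sequence length {len(seq)} != PWM width {pwm.width}")
    enc = encode(seq)
    if np.any(enc == 4):
        raise UsageError("score_window requires an ACGT-only sequence")
    lo = pwm.log_odds()
    return float(np.sum(lo[np.arange(pwm.width), enc]))


def _int_scores(pwm: PWM, granularity: int) -> np.ndarray:
    """Integerized per-position log-odds (int64); -inf mapped to a sentinel."""
    lo = pwm.log_odds()
    ints = np.full(lo.shape, _NEG_INF_INT, dtype=np.int64)
    finite = np.isfinite(lo)
    ints[finite] = np.rint(lo[finite] * granularity).astype(np.int64)
    return ints


@dataclass
class ScoreNull:
    """Exact pmf of the integerized window score under the background model.

    ``pmf[k]`` is the probability of integer score ``min_int + k`` over
    ACGT-only windows; ``p_neg_inf`` is the mass of windows whose score is
    minus infinity (they contain a zero-probability base).  ``survival[k]`` is
    ``P(S >= min_int + k)`` over the finite part.
    """

    granularity: int
    min_int: int
    pmf: np.ndarray
    p_neg_inf: float
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(self.pmf.sum()) + self.p_neg_inf
        if not np.isclose(total, 1.0, atol=1e-9):
            raise UsageError(f"null pmf mass {total} != 1")
        self.survival = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def max_int(self) -> int:
        return self.min_int + len(self.pmf) - 1

    def pvalue_int(self, score_int: int) -> float:
        """Upper-tail probability ``P(S >= score_int)``."""
        if score_int < _NEG_INF_CUTOFF:
            return 1.0
        if score_int > self.max_int:
            return 0.0
        k = max(0, score_int - self.min_int)
        return float(self.survival[k])

    def pvalue(self, score_bits: float) -> float:
        if not np.isfinite(score_bits):
            return 1.0 if score_bits < 0 else 0.0
        return self.pvalue_int(int(round(score_bits * self.granularity)))

    def min_int_for_pvalue(self, p_thresh: float) -> int:
        """Smallest integer score whose p-value is <= ``p_thresh``."""
        if p_thresh >= 1.0:
            return _NEG_INF_INT  # every window qualifies, -inf included
        idx = np.searchsorted(-self.survival, -p_thresh, side="left")
        if idx >= len(self.survival):
            return self.max_int + 1  # nothing qualifies
        return self.min_int + int(idx)


def build_score_null(pwm: PWM, granularity: int = DEFAULT_GRANULARITY) -> ScoreNull:
    """Exact null of the integerized window score via per-position convolution.

    Each position contributes a four-point score distribution under the
    background; the window score pmf is their convolution, computed densely by
    shift-and-add (exact float accumulation, no FFT).
    """
    if granularity < 100:
        raise UsageError("granularity must be >= 100 bins per bit")
    ints = _int_scores(pwm, granularity)
    bg = pwm.background
    # start from the delta at 0
    pmf = np.ones(1)
    offset = 0  # integer score of pmf[0]
    finite_mass = 1.0
    for i in range(pwm.width):
        scores = ints[i]
        finite = scores > _NEG_INF_CUTOFF
        if not np.any(finite):
            return ScoreNull(granularity, 0, np.zeros(1), 1.0)
        smin = int(scores[finite].min())
        smax = int(scores[finite].max())
        new = np.zeros(len(pmf) + (smax - smin))
        for b in range(4):
            if not finite[b] or bg[b] == 0:
                continue
            shift = int(scores[b]) - smin
            new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        offset += smin
        finite_mass *= float(bg[finite].sum())
    p_neg_inf = max(0.0, 1.0 - float(pmf.sum()))
    return ScoreNull(granularity, offset, pmf, p_neg_inf)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: window interval, strand, score (bits), p-value."""

    interval: GenomicInterval
    strand: str
    score: float
    pvalue: float
    motif_id: str = ""


def _window_int_sums(enc: np.ndarray, ints: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Integer score sums and validity mask for every window of one strand."""
    w = ints.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)  # (L-w+1, w)
    valid = ~np.any(windows == 4, axis=1)
    padded = np.hstack([ints, np.full((w, 1), _NEG_INF_INT, dtype=np.int64)])
    sums = padded[np.arange(w)[None, :], windows.astype(np.int64)].sum(axis=1)
    return sums, valid


def scan_sequence(
    pwm: PWM,
    seq: str,
    p_thresh: float = DEFAULT_P_THRESH,
    null: Optional[ScoreNull] = None,
    granularity: int = DEFAULT_GRANULARITY,
    chrom: str = "seq",
    offset: int = 0,
) -> List[MotifHit]:
    """Scan both strands for motif occurrences with p-value <= ``p_thresh``.

    The minus strand is scored on the reverse complement; a minus-strand hit
    at result coordinate ``[s, s+w)`` means the reverse complement of that
    window matches the motif.  Windows containing non-ACGT characters are
    skipped.  All qualifying hits are returned, overlapping ones included,
    sorted by (start, strand).
    """
    w = pwm.width
    if len(seq) < w:
        return []
    if null is None:
        null = build_score_null(pwm, granularity)
    ints = _int_scores(pwm, null.granularity)
    lo = pwm.log_odds()
    arange_w = np.arange(w)
    min_int = null.min_int_for_pvalue(p_thresh)

    hits: List[MotifHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        enc = encode(s)
        sums, valid = _window_int_sums(enc, ints)
        passing = np.nonzero(valid & (sums >= min_int))[0]
        for j in passing:
            if strand == "+":
                start = int(j)
            else:
                start = len(seq) - int(j) - w
            window_enc = enc[j : j + w]
            score = float(np.sum(lo[arange_w, window_enc]))
            pval = null.pvalue_int(int(sums[j]))
            iv = GenomicInterval(chrom, offset + start, offset + start + w)
            hits.append(MotifHit(iv, strand, score, pval, motif_id=pwm.id))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def motif_count(
    pwm: PWM,
    genome: Genome,
    site: GenomicInterval,
    p_thresh: float = DEFAULT_P_THRESH,
    null: Optional[ScoreNull] = None,
) -> int:
    """Number of motif occurrences inside a site window (both strands).

    Windows extending past the chromosome are counted on the clipped
    sequence.
    """
    size = genome.sizes[site.chrom]
    lo, hi = max(0, site.start), min(size, site.end)
    if hi - lo < pwm.width:
        return 0
    seq = genome.fetch(site.chrom, lo, hi)
    return len(scan_sequence(pwm, seq, p_thresh=p_thresh, null=null,
                             chrom=site.chrom, offset=lo))


# ---------------------------------------------------------------------------
# Aggregate affinity score
# ---------------------------------------------------------------------------

def aggregate_affinity_score(
    pwms: Sequence[PWM],
    genome: Genome,
    site: GenomicInterval,
    mode: str = "sum",
    nulls: Optional[Dict[str, ScoreNull]] = None,
) -> float:
    """Summed motif content of a window across PWMs, strands and offsets.

    ``mode='sum'`` (default): ``S = sum max(0, log-odds bits)`` over every
    valid offset of every listed PWM on both strands -- weak partial matches
    contribute, and adding a motif instance can only increase S.
    ``mode='count'``: number of hits under a fully relaxed p-value threshold
    (p <= 1), i.e. all scoreable windows; provided as the alternative reading
    of an unthresholded motif-content aggregate.
    """
    if mode not in ("sum", "count"):
        raise UsageError(f"unknown aggregate mode {mode!r}")
    size = genome.sizes[site.chrom]
    lo_b, hi_b = max(0, site.start), min(size, site.end)
    if hi_b <= lo_b:
        return 0.0
    seq = genome.fetch(site.chrom, lo_b, hi_b)
    if mode == "count":
        total = 0
        for pwm in pwms:
            null = (nulls or {}).get(pwm.id)
            total += len(scan_sequence(pwm, seq, p_thresh=1.0, null=null))
        return float(total)
    total = 0.0
    for pwm in pwms:
        w = pwm.width
        if len(seq) < w:
            continue
        lo = pwm.log_odds()
        finite_lo = np.where(np.isfinite(lo), lo, -np.inf)
        for s in (seq, reverse_complement(seq)):
            enc = encode(s)
            windows = np.lib.stride_tricks.sliding_window_view(enc, w)
            valid = ~np.any(windows == 4, axis=1)
            if not np.any(valid):
                continue
            idx = windows[valid].astype(np.int64)
            scores = finite_lo[np.arange(w)[None, :], idx].sum(axis=1)
            total += float(np.sum(np.clip(scores, 0.0, None)))
    return total
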