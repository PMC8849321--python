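"""PWM parsing, log-odds scoring, the exact score null, and scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pioneerkit as pk
from pioneerkit.errors import ParseError, UsageError
from pioneerkit.genome import reverse_complement
from pioneerkit.intervals import GenomicInterval
from pioneerkit.motifs import BASES, build_score_null, encode


def random_pwm(width, rng, sharp=False, pseudocount=0.1):
    counts = rng.integers(1, 50, size=(width, 4)).astype(float)
    if sharp:
        for i in range(width):
            counts[i, rng.integers(4)] += 200
    return pk.PWM.from_counts(f"rnd{width}", counts, pseudocount=pseudocount)


def consensus_pwm(seq, pseudocount=0.0):
    """Probability-1 columns spelling ``seq``."""
    counts = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        counts[i, BASES.index(b)] = 10.0
    return pk.PWM.from_counts(f"cons_{seq}", counts, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# JASPAR I/O and normalization
# ---------------------------------------------------------------------------

def test_uniform_counts_give_uniform_probs(tmp_path):
    p = tmp_path / "u.jaspar"
    p.write_text(">U uniform\nA [ 1 1 1 ]\nC [ 1 1 1 ]\nG [ 1 1 1 ]\nT [ 1 1 1 ]\n")
    pwm = pk.read_jaspar(p, pseudocount=0.0)
    assert pwm.width == 3
    assert np.allclose(pwm.probs, 0.25)


def test_pseudocount_normalization(tmp_path):
    p = tmp_path / "a.jaspar"
    p.write_text(">A\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
    pwm = pk.read_jaspar(p, pseudocount=0.1)
    assert pwm.probs[0, 0] == pytest.approx(10.1 / 10.4, abs=1e-12)
    assert pwm.probs[0, 1] == pytest.approx(0.1 / 10.4, abs=1e-12)


def test_jaspar_roundtrip_preserves_probs(tmp_path):
    rng = np.random.default_rng(1)
    pwm = random_pwm(7, rng)
    path = tmp_path / "rt.jaspar"
    pk.write_jaspar(pwm, path, scale=1.0)
    back = pk.read_jaspar(path, pseudocount=0.0)
    assert np.allclose(back.probs, pwm.probs, atol=1e-5)


def test_jaspar_rejects_ragged_and_negative(tmp_path):
    p = tmp_path / "bad.jaspar"
    p.write_text(">B\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
    with pytest.raises(ParseError):
        pk.read_jaspar(p)
    p.write_text(">B\nA [ -1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
    with pytest.raises(ParseError):
        pk.read_jaspar(p)


# ---------------------------------------------------------------------------
# score_window
# ---------------------------------------------------------------------------

def test_uniform_pwm_scores_zero():
    pwm = pk.PWM("u", np.full((6, 4), 0.25))
    assert pk.score_window(pwm, "ACGTAC") == pytest.approx(0.0, abs=1e-12)


def test_consensus_score_closed_form():
    pwm = consensus_pwm("AAA")
    assert pk.score_window(pwm, "AAA") == pytest.approx(6.0, abs=1e-12)  # 3*log2(4)


def test_score_window_matches_per_position_sum_and_biopython():
    from Bio import motifs as bio_motifs
    from Bio.Seq import Seq

    rng = np.random.default_rng(7)
    for _ in range(20):
        w = int(rng.integers(3, 12))
        counts = rng.integers(1, 40, size=(w, 4)).astype(float)
        pwm = pk.PWM.from_counts("x", counts, pseudocount=0.1)
        seq = "".join(rng.choice(list(BASES), w))
        manual = sum(
            np.log2(pwm.probs[i, BASES.index(b)] / 0.25) for i, b in enumerate(seq)
        )
        assert pk.score_window(pwm, seq) == pytest.approx(manual, abs=1e-9)
        m = bio_motifs.Motif(
            alphabet="ACGT",
            counts={b: list(counts[:, j]) for j, b in enumerate(BASES)},
        )
        m.pseudocounts = 0.1
        bio_score = float(m.pssm.calculate(Seq(seq)))
        assert pk.score_window(pwm, seq) == pytest.approx(bio_score, abs=1e-4)


def test_score_window_invariant_under_joint_permutation():
    rng = np.random.default_rng(9)
    pwm = random_pwm(8, rng)
    seq = "".join(rng.choice(list(BASES), 8))
    perm = rng.permutation(8)
    permuted = pk.PWM("p", pwm.probs[perm])
    pseq = "".join(seq[i] for i in perm)
    assert pk.score_window(permuted, pseq) == pytest.approx(
        pk.score_window(pwm, seq), abs=1e-12
    )


# ---------------------------------------------------------------------------
# exact score null
# ---------------------------------------------------------------------------

def enumeration_null(pwm, granularity=1000):
    """Oracle pmf: exhaustive enumeration of all 4^w windows."""
    lo = pwm.log_odds()
    pmf = {}
    p_inf = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        prob = float(np.prod([pwm.background[b] for b in word]))
        scores = [lo[i, b] for i, b in enumerate(word)]
        if not all(np.isfinite(scores)):
            p_inf += prob
            continue
        key = int(sum(int(round(s * granularity)) for s in scores))
        pmf[key] = pmf.get(key, 0.0) + prob
    return pmf, p_inf


@pytest.mark.parametrize("width", [3, 5, 6])
def test_null_pmf_matches_enumeration(width):
    rng = np.random.default_rng(width)
    pwm = random_pwm(width, rng, sharp=True)
    null = build_score_null(pwm)
    oracle, p_inf = enumeration_null(pwm)
    total_diff = abs(null.p_neg_inf - p_inf)
    for k, p in oracle.items():
        total_diff += abs(null.pmf[k - null.min_int] - p)
    # any pmf bin not in the oracle must be ~0
    covered = {k - null.min_int for k in oracle}
    for idx in range(len(null.pmf)):
        if idx not in covered:
            total_diff += abs(null.pmf[idx])
    assert total_diff < 1e-9


def test_null_consensus_max_probability_closed_form():
    pwm = consensus_pwm("ACGTA")  # probability-1 columns, width 5
    null = build_score_null(pwm)
    assert null.pvalue_int(null.max_int) == pytest.approx((1 / 4) ** 5, abs=1e-15)
    assert null.pvalue(float("-inf")) == 1.0


def test_null_pvalues_monotone_in_score():
    rng = np.random.default_rng(5)
    pwm = random_pwm(7, rng)
    null = build_score_null(pwm)
    scores = np.arange(null.min_int, null.max_int + 1, 37)
    ps = [null.pvalue_int(int(s)) for s in scores]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert null.pvalue_int(null.min_int) == pytest.approx(1.0, abs=1e-9)


def test_nonuniform_background_null_still_normalized():
    rng = np.random.default_rng(6)
    counts = rng.integers(1, 30, size=(5, 4)).astype(float)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    pwm = pk.PWM.from_counts("bg", counts, pseudocount=0.1, background=bg)
    null = build_score_null(pwm)
    oracle, p_inf = enumeration_null(pwm)
    diff = sum(abs(null.pmf[k - null.min_int] - p) for k, p in oracle.items())
    assert diff < 1e-9


# ---------------------------------------------------------------------------
# scan_sequence
# ---------------------------------------------------------------------------

def test_scan_all_n_sequence_yields_nothing():
    pwm = consensus_pwm("ACGTA")
    assert pk.scan_sequence(pwm, "N" * 200) == []


def test_scan_strand_symmetry():
    rng = np.random.default_rng(11)
    pwm = random_pwm(6, rng, sharp=True)
    seq = "".join(rng.choice(list(BASES), 300))
    fwd = pk.scan_sequence(pwm, seq, p_thresh=0.01)
    rev = pk.scan_sequence(pwm, reverse_complement(seq), p_thresh=0.01)
    flip = {"+": "-", "-": "+"}
    mirrored = sorted(
        (len(seq) - h.interval.end, flip[h.strand], round(h.score, 9)) for h in rev
    )
    assert sorted((h.interval.start, h.strand, round(h.score, 9)) for h in fwd) == mirrored


def test_scan_threshold_one_counts_every_window():
    rng = np.random.default_rng(12)
    pwm = random_pwm(5, rng)
    seq = "".join(rng.choice(list(BASES), 60)) + "N" + "".join(rng.choice(list(BASES), 20))
    hits = pk.scan_sequence(pwm, seq, p_thresh=1.0)
    L, w = len(seq), 5
    skipped_per_strand = w  # windows overlapping the single N
    assert len(hits) == 2 * (L - w + 1) - 2 * skipped_per_strand


def test_scan_finds_planted_consensus():
    pwm = consensus_pwm("TTGACCA")
    seq = "A" * 100 + "TTGACCA" + "C" * 80 + reverse_complement("TTGACCA") + "A" * 60
    hits = pk.scan_sequence(pwm, seq)
    assert {(h.interval.start, h.strand) for h in hits} == {(100, "+"), (187, "-")}


def test_expected_false_hit_rate_on_background():
    """Hits on background sequence arrive at ~2 * (L - w + 1) * p."""
    rng = np.random.default_rng(13)
    pwm = random_pwm(8, rng, sharp=True)
    null = build_score_null(pwm)
    p = 1e-2
    L, n_seq = 1000, 60
    total = 0
    for _ in range(n_seq):
        seq = "".join(rng.choice(list(BASES), L))
        total += len(pk.scan_sequence(pwm, seq, p_thresh=p, null=null))
    lam_per_window = null.pvalue_int(null.min_int_for_pvalue(p))
    expected = 2 * (L - 8 + 1) * lam_per_window * n_seq
    sd = np.sqrt(expected)
    assert abs(total - expected) < 5 * sd


# ---------------------------------------------------------------------------
# motif_count / aggregate score
# ---------------------------------------------------------------------------

def _genome_with(seq, chrom="c"):
    return pk.Genome({chrom: seq})


def test_motif_count_revcomp_invariant_and_planted():
    rng = np.random.default_rng(14)
    bgseq = "".join(rng.choice(list(BASES), 500))
    cons = "TTGACCAG"
    pwm = consensus_pwm(cons)
    seq = bgseq[:50] + cons + bgseq[58:200] + cons + bgseq[208:350] + cons + bgseq[358:]
    site = GenomicInterval("c", 0, 500)
    n_fwd = pk.motif_count(pwm, _genome_with(seq), site)
    n_rev = pk.motif_count(pwm, _genome_with(reverse_complement(seq)), site)
    assert n_fwd >= 3
    assert n_fwd == n_rev


def test_motif_count_background_window_nearly_empty():
    """False hits in a background 500-bp window are Poisson with mean ~1."""
    rng = np.random.default_rng(15)
    pwm = random_pwm(9, rng, sharp=True)
    null = build_score_null(pwm)
    seq = "".join(rng.choice(list(BASES), 500))
    n = pk.motif_count(pwm, _genome_with(seq), GenomicInterval("c", 0, 500), null=null)
    assert n <= 4


def test_aggregate_all_n_window_is_zero():
    pwm = consensus_pwm("ACGT" + "A")
    g = _genome_with("N" * 500)
    assert pk.aggregate_affinity_score([pwm], g, GenomicInterval("c", 0, 500)) == 0.0


def test_aggregate_monotone_in_planted_instances():
    rng = np.random.default_rng(16)
    pwm = random_pwm(8, rng, sharp=True)
    base = "".join(rng.choice(list(BASES), 500))
    inst = pwm.consensus()
    with_extra = base[:100] + inst + base[108:]
    site = GenomicInterval("c", 0, 500)
    s0 = pk.aggregate_affinity_score([pwm], _genome_with(base), site)
    s1 = pk.aggregate_affinity_score([pwm], _genome_with(with_extra), site)
    assert s1 >= s0


def test_aggregate_matches_brute_force_on_toy():
    rng = np.random.default_rng(17)
    pwm = random_pwm(4, rng)
    seq = "".join(rng.choice(list(BASES), 20))
    lo = pwm.log_odds()
    expected = 0.0
    for s in (seq, reverse_complement(seq)):
        for off in range(len(s) - 4 + 1):
            sc = sum(lo[i, BASES.index(s[off + i])] for i in range(4))
            expected += max(0.0, sc)
    got = pk.aggregate_affinity_score([pwm], _genome_with(seq), GenomicInterval("c", 0, 20))
    assert got == pytest.approx(expected, abs=1e-9)


def test_aggregate_count_mode_counts_scoreable_windows():
    rng = np.random.default_rng(18)
    pwm = random_pwm(5, rng)
    seq = "".join(rng.choice(list(BASES), 50))
    got = pk.aggregate_affinity_score([pwm], _genome_with(seq),
                                      GenomicInterval("c", 0, 50), mode="count")
    assert got == 2 * (50 - 5 + 1)
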