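"""Scan a sequence for motif occurrences with exactly calibrated p-values.

The scanner slides a PWM over both strands and keeps windows whose log-odds
score is significant under the exact null distribution of the score
(obtained by convolving per-position score distributions, not by sampling).
"""

import numpy as np

import pioneerkit as pk

pwms = pk.default_pwms()
foxa1 = pwms["FOXA1"]
print(f"PWM {foxa1.id}: width {foxa1.width}, consensus {foxa1.consensus()}")

null = pk.build_score_null(foxa1)
print(f"exact null: P(score = max) = {null.pvalue_int(null.max_int):.3e}")

# a 500-bp random window with two planted consensus instances
rng = np.random.default_rng(0)
seq = list("".join(rng.choice(list("ACGT"), 500)))
for pos in (120, 300):
    seq[pos : pos + foxa1.width] = foxa1.consensus()
seq = "".join(seq)

hits = pk.scan_sequence(foxa1, seq, p_thresh=1e-3)
print(f"\nhits at p <= 1e-3 ({len(hits)}):")
for h in hits:
    print(f"  pos {h.interval.start:4d}  strand {h.strand}  "
          f"score {h.score:6.2f} bits  p = {h.pvalue:.2e}")
# The two planted instances are recovered at the planted offsets; any extra
# hit is a chance match, expected at rate ~ 2 * 489 * 1e-3 ~ 1 per window.
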