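# pioneerkit

Does "pioneer activity" — a transcription factor's ability to bind and open
nucleosome-occluded DNA — belong to a special class of factors, or does it
fall out of ordinary sequence affinity?  `pioneerkit` is a toolkit for
testing that question the way an ectopic-expression experiment does:
classify each binding site by whether it was accessible before induction,
sort co-bound sites into *pioneered* versus *cooperative* classes, ask which
silent tissue-specific genes were activated, and then check whether plain
motif content predicts where binding happened.

Everything runs end-to-end on synthetic genomes with planted ground truth,
so every stage can be scored exactly; the same functions accept real peak
calls (BED), count matrices (TSV) and JASPAR PFMs.

## What it computes

Given binding peak sets for two factors (here called FOXA1 and HNF4A)
expressed alone and together, plus pre-/post-induction accessibility peaks:

- **Accessibility classes** — a bound site is *inaccessible* iff it overlaps
  no pre-induction accessibility peak, and *opened* iff it was inaccessible
  and overlaps a post-induction peak.
- **Co-binding taxonomy** — loci where the two factors' co-expression peaks
  overlap are classed FP (bound by FOXA1 alone too: "FOXA1 pioneered"),
  HP, BOTH, or CB (bound by neither alone: "cooperatively bound").
- **Activation calls** — a gene is *activated* when log2 fold change ≥ 1
  from a baseline of < 50 normalized reads (median-of-ratios
  normalization); activated sets are tested against fourfold-rule
  tissue-enriched gene sets with the upper-tail hypergeometric
  P(X ≥ k | N, K, n), computed in log space.
- **Motif analysis** — FIMO-style PWM scanning on 500-bp windows centred on
  binding sites, with exact p-values from the convolved null distribution of
  the integerized log-odds score S = Σᵢ log₂(pᵢ(bᵢ)/q(bᵢ)); and the
  **aggregate affinity score** Σ max(0, score) over all offsets, strands and
  PWMs, whose bare threshold is swept into ROC curves (AUC = normalized
  Mann–Whitney U) to ask how predictable binding is from sequence alone.
- **Synthetic data** — a generator that plants all of the above: disjoint
  500-bp site windows with class-specific motif multiplicities (defaults:
  FOXA1-pioneered sites carry 2–4 FOXA1 motifs, HNF4A-pioneered sites 3–6
  HNF4A motifs, cooperative sites ≤ 1 of either), consistent peak tracks
  with replicate jitter/dropout noise, negative-binomial counts with planted
  activation, and a tissue table with planted fourfold enrichment — plus a
  ledger recording the truth for every site.

## Worked example

```bash
python examples/03_cobinding_taxonomy.py
```

```
co-bound sites: 159
  FP   recovered  29  (planted 30)
  HP   recovered  46  (planted 50)
  BOTH recovered  55  (planted 55)
  CB   recovered  29  (planted 30)

full-ledger recovery: 95.4% of 285 planted sites
```

The simulated dataset planted 165 co-bound sites; after replicate merging
(peaks must reproduce in both replicates), 159 survive the default dropout
noise and every surviving site receives the correct FP/HP/BOTH/CB label.
With noise disabled, recovery is exactly 100%.

```bash
python examples/05_affinity_roc.py
```

```
threshold-classifier AUCs (motif content -> binding):
  FOXA1_accessible_vs_random         AUC 0.728   (20 vs 20)
  FOXA1_inaccessible_vs_random       AUC 0.884   (125 vs 125)
  FP_vs_CB                           AUC 0.890   (30 vs 30)
  HNF4A_accessible_vs_random         AUC 0.950   (20 vs 20)
  HNF4A_inaccessible_vs_random       AUC 0.996   (145 vs 145)
  HP_vs_CB                           AUC 0.989   (50 vs 30)
  cobound_inaccessible_vs_random     AUC 0.901   (165 vs 165)
```

Aggregate motif content predicts binding at previously *inaccessible* sites
far better than at accessible ones (where fewer motifs suffice), and
separates pioneered from cooperative co-binding — the signatures an
affinity-based account of pioneering predicts.

Other examples: `01_simulate_dataset.py` (the generator and its ledger),
`02_motif_scan.py` (exact-p-value scanning), `04_activation_enrichment.py`
(activation calls and hypergeometric enrichment).

## Command line

```bash
pioneerkit simulate --out data/              # synthetic dataset + manifest
pioneerkit analyze  --data data/ --out out/  # all stages, one TSV/JSON each
pioneerkit report   --results out/           # fold into summary.json
```

Runs are bit-reproducible given the config and seed.

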