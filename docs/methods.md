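# Methods

This note documents the models, rules and numerical choices behind
`pioneerkit`, and what the synthetic benchmark does and does not establish.

## The analytical question

Two transcription factors are expressed in a cell type where both are
normally silent — separately and together — and their binding, the
chromatin accessibility before and after induction, and the transcriptional
response are measured.  The classical pioneer-factor account predicts an
asymmetry: a designated pioneer binds closed chromatin first and a
non-pioneer follows.  The affinity account predicts no categorical
asymmetry: any factor binds closed chromatin when the site offers enough
motif content.  The pipeline operationalizes the comparisons that
distinguish these accounts.

## Interval conventions

All coordinates are 0-based half-open (BED).  Two intervals overlap iff
they share ≥ 1 bp; no minimum-overlap fraction is imposed anywhere, matching
the default of standard interval tooling.  **Replicate merging** groups
transitively overlapping peaks from the two replicates and keeps only groups
supported by both, emitting the union span.  This is a deliberately
transparent reproducibility filter; it replaces model-based irreproducible
discovery rate filtering, whose fitted mixture model is out of scope here.
**Co-bound sites** use the same dual-source clustering applied to the two
factors' co-expression tracks.  Site windows for sequence analysis are 500 bp
centred on the peak midpoint (`mid = start + ⌊len/2⌋`; merged peaks carry no
summit, so the midpoint is the only well-defined anchor), clipped at
chromosome ends with a flag.  Gene attribution is strand-independent:
±25 kb around the TSS for single-factor sites, ±50 kb for co-bound sites
(co-binding is rarer, so a wider net is used).

## Accessibility and co-binding classes

A bound site is *accessible* iff it overlaps ≥ 1 merged pre-induction
accessibility peak, else *inaccessible*; an inaccessible bound site is
*opened* iff it overlaps a merged post-induction peak.  "Opened" is defined
by peak overlap rather than by a differential signal model: read-level
quantification is out of scope, and the overlap reading matches how
induced-accessibility heatmaps are interpreted.  Each co-bound site gets
exactly one label from {FP, HP, BOTH, CB} according to which single-
expression tracks overlap it; the partition property (labels exhaust and
exclude) and the FP↔HP symmetry under swapping the factors are tested.
Chromatin-state profiling assigns each site to the segmentation state with
maximal bp overlap, ties broken toward the leftmost-starting segment
(deterministic), with an explicit `Unassigned` category.

## Expression rules

Counts are normalized by median-of-ratios size factors (the standard
RNA-seq convention): factor_j = median over all-positive genes of
counts[g,j] / geometric-mean(counts[g,·]).  Genes with < 10 total raw reads
are dropped first; the enrichment universe N is the set of genes that
survive this filter — the genes that *could* have been called.  Log2 fold
change uses pseudocount 1, keeping it finite at zero baselines.  No
dispersion shrinkage is re-implemented: planted effects (and the intended
use) sit far from the decision thresholds, so a transparent estimator is
preferable, and an externally computed per-gene table with the same columns
(plus optional `padj`, which then gates calls at 0.05) can be supplied.

*Upregulated*: log2FC ≥ 1.  *Activated*: upregulated and uninduced mean
< 50 normalized reads.  *Tissue-enriched* (fourfold rule): expression in the
tissue ≥ 4× the maximum in any other tissue (boundary inclusive; positive
vs all-zero counts as enriched).  Enrichment of the activated set in a
tissue set is the upper-tail hypergeometric P(X ≥ k), computed via the
log-survival function so that genome-scale arguments (N ≈ 2·10⁴) cannot
underflow.

## Motif model

PWMs are parsed from JASPAR PFM text; counts are normalized per column as
(count + pc) / (total + 4·pc) with pseudocount pc = 0.1.  The default
background is uniform; the pipeline stage calibrates the background to the
analyzed genome's own base composition (a 0-order sequence background, the
convention of FIMO-class scanners), which matters on AT-rich genomes where
a flat background inflates the scores of AT-rich motifs.

Scores are log-odds in bits.  P-values are **exact**: per-position scores
are integerized at 1000 bins/bit and the null pmf of the window score under
the background is the convolution of the per-position four-point
distributions (dense shift-and-add, no FFT, so the pmf matches exhaustive
enumeration to < 1e-9 total deviation).  Zero-probability bases (possible
at pseudocount 0) give score −∞; such windows carry p = 1 and their mass is
tracked separately.  Scanning covers both strands (minus strand scored on
the reverse complement), skips windows containing non-ACGT characters, and
keeps *all* hits at p ≤ 1e-3 — overlapping and same-offset two-strand hits
included, again following scanner convention.

The **aggregate affinity score** of a window is S = Σ max(0, score) over
all offsets, both strands and the listed PWMs.  This is the "sum the motif
content with a fully permissive threshold" idea made well-defined: a
literal p-threshold of 0 admits nothing, so clipping at background odds is
used — every window that looks even weakly motif-like contributes, S is
finite, and planting an extra instance can only increase S.  A hit-count
aggregate at p ≤ 1 is exposed as an alternative (`aggregate_mode="count"`),
but note it degenerates to the number of scoreable windows; it is kept only
as the other literal reading of an unthresholded aggregate.

## ROC analysis

The classifier is a bare threshold: score ≥ t ⇒ bound.  Sweeping t over the
observed scores (ties as single steps) and integrating by trapezoid gives
an AUC identical to the Mann–Whitney U statistic normalized by n₊·n₋ —
asserted to 1e-12 in the tests.  Negative sets are drawn 1:1 with
positives: length-matched windows sampled uniformly from sequence that is
neither accessible *nor part of any assayed binding site*.  The second
exclusion is a toy-genome necessity: planted sites occupy ~20% of the
synthetic genome, so "random inaccessible" draws would otherwise hit
planted motifs; on a real genome binding sites are a negligible fraction
and the exclusion is immaterial.  Pioneered-vs-cooperative comparisons
(FP vs CB, HP vs CB) use only the relevant factor's PWM.

## The synthetic benchmark

The generator emulates the study conditions end to end; its defaults are
the reference conditions used by the tests and the acceptance script.

| Parameter | Default | Why |
| --- | --- | --- |
| genome | 3 × 2 Mb, 41% GC | large enough for ~2,500 disjoint windows plus background; mammalian-like GC |
| site windows | 500 bp, ≥ 300 bp apart | the analysis window; spacing keeps peaks from chaining |
| co-bound class mix | FP 253 / HP 425 / BOTH 474 / CB 274 | proportional (1/8 scale) to a genome-wide co-binding survey |
| single-factor sites | 300 inaccessible + 150 accessible per factor | inaccessible binding dominates in the ectopic setting |
| motif multiplicities | FOXA1-pioneered 2–4, HNF4A-pioneered 3–6, CB ≤ 1 each; accessible sites 1–2 / 1–3 | the asymmetry under test: the higher-affinity factor needs fewer motifs; open chromatin needs fewer still |
| planted instances | PWM-sampled, non-overlapping, random strand, resampled until detectable at p ≤ 1e-3 | multiplicity statements refer to *callable* occurrences; a consensus-forcing mode exists for exact tests |
| PWMs | synthetic FOXA1-like (12 bp) and HNF4A-like (13 bp) matrices | stand-ins with the information content (~11–13 bits) typical of curated motifs for these factors; labelled synthetic, not the database entries |
| replicate noise | jitter sd 10 bp, dropout 0.005/peak/replicate | ~99% replicate concordance; the benchmark targets ≥ 95% full-ledger recovery, and dual-replicate merging makes recovery ≈ ((1−d)²)ᵏ across the k tracks a class implies, so d must be small |
| counts | NB, dispersion 10, 3+3 replicates; baselines log-normal around 200; activated genes: baseline 5, log2FC 3, 60 of 5,000 genes | silent-to-active activation far from the call thresholds; log-normal baselines exercise the < 50-reads rule |
| tissue table | 6 tissues; liver set 242 (⊇ activated), intestine 122; enriched value = exactly 4 × max-other, baselines U(5, 15) | fourfold boundary is sharp and serialization-exact; baselines can never fake enrichment (max/min ≤ 3) |

All randomness flows from one seeded generator in a fixed draw order
(genome → sites → genes → peaks → counts → tissue → segmentation);
identical configs give byte-identical output files.

**What passing shows, and what it does not.**  The benchmark has i.i.d.
background sequence, perfectly disjoint sites, noise only as boundary
jitter and peak dropout, and activation planted directly at linked sites.
Recovery and AUC results therefore validate the *logic and exactness* of
the pipeline — not its robustness to real-data pathologies (repeat
sequence, copy-number artefacts, overlapping regulatory elements, indirect
binding, batch effects), which the generator deliberately does not model.

## Numerical choices and degenerate inputs

- Score-null granularity 1000 bins/bit; scanning compares integer sums
  against the integer threshold derived from the requested p-value, so scan
  and null are always consistent.
- Midpoint of odd-length sites uses floor; windows clip at chromosome ends
  with a flag rather than being rejected.
- Random-window sampling rejects draws with ≥ 10% non-ACGT and raises after
  1000 attempts per requested window, reporting how many were placed.
- `roc_curve` and `compare_groups` refuse empty groups; enrichment refuses
  inconsistent (k, K, n, N).
- The tissue table is written with `%.17g` floats and read back with
  round-trip parsing; together with the ×4 boundary being an exact binary
  operation, the planted fourfold rule survives serialization bit-exactly.

## Problem sizes

The default simulation (2,526 sites, 5,000 genes, 6 Mb) analyzes in ~10 s;
the test suite and the acceptance script each complete in well under two
minutes on a single CPU.  These sizes were chosen so that every class
contains hundreds of sites (stable medians and AUCs) while the whole
benchmark stays interactive.
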