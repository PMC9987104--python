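# Methods

## Two-isoform PDUI model

A gene's 3'UTR coverage is modelled as the superposition of a long
isoform covering all positions at `w_L` reads/base and a short isoform
covering positions before the proximal poly(A) site `P` at `w_S`
reads/base.  In transcript orientation (offset 0 = 5' end of the
3'UTR; minus-strand tracks reversed on load):

    E[depth(x)] = w_S · 1[x < P] + w_L,   w_S, w_L ≥ 0.

`estimate_pdui` searches every integer breakpoint in
`[end_margin, L − end_margin)` — no grid coarsening — and solves the
per-breakpoint non-negative least squares in closed form: with segment
means `m1` (before `P`) and `m2` (after), the unconstrained solution is
`w_S = m1 − m2, w_L = m2`; when `m1 < m2` the non-negativity constraint
is active and the KKT conditions give `w_S = 0, w_L = mean(depth)`.
The breakpoint minimising SSE wins; exact ties resolve to the most
proximal (5'-most) site, so output is deterministic.  PDUI is
`w_L / (w_L + w_S)`.

Parameters:

* `end_margin` (nt, default 50) — excludes degenerate one-sided fits at
  the UTR edges.  Must satisfy `2·end_margin < L`.
* `min_mean_depth` (reads/base, default 5) — below this the estimate is
  unstable and the record is returned as `low_coverage` with PDUI = NA
  rather than a number.

A brute-force reference (`apakit.reference.brute_force_pdui`) loops
over breakpoints, reconstructs each fitted profile and accumulates
residuals directly; it shares no code path with the vectorized
estimator and is the oracle in the validation studies.  Its closed-form
step is itself checked against `scipy.optimize.nnls` in the test suite.

## APA change calls

ΔPDUI = mean PDUI(case) − mean PDUI(control); positive = lengthening.
Significance uses Fisher's exact test on pooled isoform read counts
(`round(abundance × UTR length)` summed over samples, 2×2 two-sided).
A call additionally requires |ΔPDUI| ≥ `min_abs_delta` (default 0.05).
The test is count-natural and needs no replicates, matching the
estimator's abundance semantics; raw p-values are the default
(BH correction is available in the DEG stage, where a genome-wide
family exists).  Zero pooled counts in either condition yield
p = 1 / unchanged, not an error.

Per-sample APA burden (`apa_event_counts`): gene g is a lengthening
event in sample s iff `PDUI(g,s) − reference(g) ≥ event_threshold`
(default 0.2), shortening symmetric.  The default reference is the
per-gene cohort median — appropriate for tumor-only cohorts — with a
paired-normal reference available when pairing metadata exists.

## Cohort landscape and regulator screen

* **Clustering** — agglomerative, average linkage, cut at k = 3.
  Genes with ≥ 20% missing values are dropped; distances are
  pairwise-complete Euclidean rescaled to the full gene count.
  Clusters are relabelled A/B/C by descending mean PDUI, so "A = long
  3'UTRs" holds by construction.  Indistinguishable samples (or a
  degenerate tree cut) trigger a deterministic contiguous split with a
  loud warning instead of a crash.
* **Differential expression** — two-sided Wilcoxon rank-sum on
  log2(expr+1) per gene between subgroups C and A, BH-FDR; fold change
  is the raw group-mean ratio (pseudocount 1 only when a mean is 0).
  Thresholds FDR < 0.05 and |log2FC| > 1 are configurable.  The test
  choice favours distribution-robustness on cohort expression; no
  claim is made that it is the only reasonable one.
* **Gene-set intersection** — membership is the union of the supplied
  sets; down-in-C DEGs become candidate lengthen-regulators, up-in-C
  candidate shorten-regulators.  Identifier-namespace mismatches are
  reported, never silently dropped.
* **Correlation screen** — Pearson r of candidate expression against
  the role-matched count series (lengthen ↔ n_lengthened,
  shorten ↔ n_shortened); keep |r| > 0.3, p < 0.05.  Zero-variance
  expression is excluded with a warning (r undefined).
* **Core-factor overlap** — intersection with the supplied core-APA
  list, ranked by descending |r|, ties broken lexicographically by
  gene id; rank 1 is the reported key regulator.

Every stage's output gene set is a subset of its input, so the screen
is monotone by construction.

## PAS typing

The scanner tests every 6-nt window against the hexamer alphabet
(overlaps reported, N never matches, RNA U mapped to T).  The default
alphabet is canonical AATAAA plus the 12 widely reported human
variants (ATTAAA, TATAAA, AGTAAA, AATACA, CATAAA, AATATA, GATAAA,
AATGAA, AATAGA, ACTAAA, AAGAAA, AATAAG); it is fully overridable
because variant inventories differ between studies.

Proximal/distal split: the 3'-most site anchors the distal cluster and
any site within `distal_window` (default 50 nt) of it is distal; the
rationale is that the distal PAS defines the long-isoform end and
signals co-located with it are part of the same cleavage region.
Genes with fewer than two sites have no proximal region and stay
unclassified — consistent with the funnel's ≥ 2 PAS criterion.  Types:
a = proximal has only non-canonical signals, b = both, c = only
canonical; the a+b share is the proportion of genes with a proximal
non-canonical PAS.  Classification is invariant to duplicate sites and
input order.

## Target funnel and quantitation

A gene is selected iff (1) total PAS count ≥ 2, (2) upregulated in
tumor, and (3) called lengthened at raw p < 0.001.  Criteria a gene
cannot be evaluated on fail closed (screening conservatism).  The
`criteria` parameter runs any sub-conjunction, which is how the
superset property (dropping a criterion can only add genes) is
verified.  `ddct_relative_expression` implements 2^−ΔΔCT;
`long_to_total_ratio` is long/total with a 1e−9 clipping tolerance and
coincides with PDUI when the signals are isoform abundances.

## Synthetic data: what it emulates and what it does not

* **Coverage** — exact step profiles with optional Poisson per-base
  counts.  Poisson is the only noise model offered: read counts are
  non-negative integers, and Gaussian jitter would break that.
* **Cohort** (defaults: 500 genes × 60 samples, subgroups 20/20/20) —
  per-gene baseline PDUI uniform on [0.35, 0.65]; subgroup offsets
  ±`subgroup_shift`/2 (default 0.25 between A and C); Gaussian PDUI
  noise sd 0.02; per-sample planted lengthening/shortening events of
  magnitude 0.35 at rates 25 ± 15 per sample (lengthening enriched in
  A, shortening in C, sd 4), drawn from a disjoint gene pool per
  sample.  Event magnitude (0.35) clears the 0.2 detection threshold
  from any subgroup baseline while subgroup offsets alone (≤ 0.125)
  never do, so with the PDUI noise switched off the detected event
  counts equal the planted ones exactly.  Expression is log-normal
  (log2 mean 6.6, sd 0.5); 20 planted DEGs get a ±2.5 log2FC subgroup
  contrast; regulator expression is driven by the realized event
  counts with a log2 gain of 0.8 and a noise level chosen analytically
  so the *raw-scale* Pearson correlation with the counts is centred on
  `regulator_effect` (default 0.6) after log-normal attenuation — near
  effect = 1 this inversion saturates at ≈ 0.85.  The null
  configuration zeroes the subgroup shift, the event-rate spread, the
  DEG contrast and the regulator effect, leaving label-free matrices.
  The generator's marginals are a stand-in, not a claim of realism:
  real tumor PDUI distributions are heavier-tailed and gene-correlated,
  real expression has library-size and batch structure, and real APA
  events are not independent across samples.  Passing tests therefore
  demonstrate correctness of the machinery on its stated model, not
  performance on any particular cohort.
* **Sequences** — uniform-ACGT backgrounds with accidental alphabet
  matches scrubbed by targeted point mutations (position and base
  randomized, since contexts like `AATA_A` make some single positions
  unfixable), so a full scan finds exactly the planted sites; each
  gene carries one distal canonical PAS plus its type-defining
  proximal inventory, spaced ≥ 12 nt so windows never conflate.
* **Funnel inputs** — exactly `n_selected` all-pass genes; the
  remainder cycle through all seven failure patterns so every single
  criterion excludes at least one gene that passes the other two.

All generators take one explicit integer seed; no global RNG state.

## Validation studies and problem sizes

`apakit.validation` (driven by `scripts/acceptance.py` and the test
suite) runs: oracle agreement on 500 random Poisson profiles
(L ≤ 300, margin 20); recovery on 200 simulations (L = 400,
100 reads/base total, true PDUI in [0.2, 0.8] so both isoforms are
present and the breakpoint is identifiable); 50 cohort runs each for
subgroup recovery (ARI ≥ 0.9 with correct A label) and rank-1
key-regulator recovery; 200 null-cohort runs with two signal-free
candidates each, compared against the analytic level of the combined
|r| > 0.3 ∧ p < 0.05 rule (P(|r| > 0.3) under the null t-distribution
at n = 60, ≈ 0.020 — the binomial check deliberately uses a modest
trial count because the t-tail is only approximate for log-normal
expression); 1000 random sequences for the scanner oracle; a
419/419/162 typed sequence set (a+b share 83.8%) for round-trip and
proportion recovery; and one 500-gene funnel with 47 planted targets.

## Known limitations

* The estimator fits exactly two isoforms; genes with ≥ 3 used PASs
  get a single compromise breakpoint.
* Breakpoint precision degrades as PDUI approaches 1 (the short
  isoform's step vanishes into the noise floor); the recovery study's
  PDUI range reflects where the parameter is identifiable.
* Fisher's exact on pooled counts treats reads as independent;
  overdispersion across replicates is not modelled.
* The clustering relabelling assumes mean PDUI separates the groups;
  for cohorts clustered by something other than global 3'UTR length
  the A/B/C semantics would not be meaningful.
* GTF support extracts `three_prime_utr` features only; annotation
  without explicit UTR features must be converted to BED first.
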