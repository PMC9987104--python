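# apakit

Alternative polyadenylation (APA) analysis for bulk RNA-seq: PDUI
estimation from 3'UTR coverage, cohort clustering by APA landscape,
regulator screening, polyadenylation-signal (PAS) typing, and a
three-criterion APA-target funnel — with a synthetic-data generator
that plants ground truth for every stage.

## Who this is for

Most human genes carry several polyadenylation signals in their 3'UTR,
so one gene yields mRNA isoforms that differ only in 3'UTR length.
Tumors commonly shift toward proximal poly(A)-site usage (shorter
3'UTRs, fewer miRNA binding sites); finding which RNA-binding factors
drive that shift, and which genes they act on, is a standard
computational task in cancer transcriptomics. `apakit` packages that
workflow as a tested Python library for people who want to run it on
coverage tracks and PDUI/expression matrices — or to benchmark it on
simulated data where the right answer is known.

## The model

For a gene with one proximal and one distal poly(A) site, per-base
3'UTR coverage in transcript orientation is modelled as a step:

    depth(x) = w_S + w_L   for x <  P        (short + long isoform)
    depth(x) = w_L         for x >= P        (long isoform only)

For every candidate breakpoint `P` the non-negative least-squares fit
of `(w_S, w_L)` is closed-form in the two segment means; the `P`
minimising the residual sum of squares is reported with

    PDUI = w_L / (w_L + w_S)

the *percentage of distal poly(A) site usage*: near 1 = long 3'UTR,
near 0 = short.  ΔPDUI = mean PDUI(case) − mean PDUI(control) calls a
gene lengthened (>0) or shortened (<0), with significance from
Fisher's exact test on pooled estimated isoform read counts.

On top of the estimator sit four analysis stages:

1. **Landscape** — hierarchical clustering of cohort samples on the
   gene × sample PDUI matrix into subgroups A/B/C (A = longest 3'UTRs).
2. **Regulator screen** — Wilcoxon differential expression between the
   extreme subgroups (BH-FDR), intersection with APA-related gene
   sets, Pearson correlation of candidate expression with each
   sample's count of 3'UTR lengthening/shortening events
   (keep |r| > 0.3, p < 0.05), and overlap with the core APA
   machinery, ranked by |r|.
3. **PAS typing** — hexamer scan (canonical AATAAA plus 12
   non-canonical variants, overridable) and classification of each
   gene's proximal 3'UTR inventory: type a (only non-canonical),
   b (both), c (only canonical).
4. **Target funnel** — a gene is nominated as an APA target when it
   has ≥ 2 PASs, is upregulated in tumor, and lengthens significantly
   (p < 0.001) upon regulator overexpression.  Utilities for the qPCR
   side (2^−ΔΔCT, long-transcript-to-total-transcript ratio) close the
   loop to wet-lab validation.

## Worked example

```sh
python examples/02_cohort_screen.py
```

```
clustering: ARI vs planted subgroups = 1.000
subgroup mean PDUI: {'A': 0.643, 'B': 0.499, 'C': 0.354}
DEG (C vs A): 12 up, 12 down
gene-set intersection: 4 candidates
correlation screen (|r|>0.3, p<0.05): 4 shortlisted
key regulator: G0000 (r=0.584); planted: G0000
```

The simulated cohort (500 genes × 60 samples, three subgroups of 20
with a 0.25 mean-PDUI gap) is clustered perfectly (adjusted Rand index
1.0), subgroup A has the highest mean PDUI as the label contract
requires, and the screen's rank-1 core-factor hit is exactly the
planted key regulator, with an observed correlation (0.584) close to
the planted effect of 0.6.  The other example scripts cover PDUI
estimation from coverage (`01`), PAS typing (`03`, reporting the
proximal-non-canonical share of a planted 84%/16% set), and the target
funnel plus qPCR utilities (`04`).

A thin CLI wraps the same stages for shell use:

```sh
apakit run-all --outdir out --seed 42     # simulate + all stages + report
apakit pdui --bedgraph cov.bedgraph --annotation utrs.bed --out pdui.tsv
apakit screen --pdui pdui.tsv --expr expr.tsv \
    --genesets sets.gmt --core-factors core.txt --outdir screen/
```

`run-all` writes `report.json` naming the recovered key regulator;
identical config + seed reproduces byte-identical outputs.

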