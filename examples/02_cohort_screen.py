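"""Cluster a PDUI cohort and screen for the key APA regulator.

Simulates the default cohort (500 genes x 60 samples, three subgroups
of 20 with a 0.25 mean-PDUI gap, planted regulators at correlation
0.6), then runs the full screen: hierarchical clustering, differential
expression between the extreme subgroups, gene-set intersection,
expression-vs-APA-burden correlation, and core-factor overlap.
"""

from sklearn.metrics import adjusted_rand_score

from apakit import (
    apa_event_counts,
    cluster_samples,
    correlation_screen,
    differential_expression,
    intersect_genesets,
    make_genesets,
    overlap_core_factors,
    simulate_cohort,
)

pdui, expr, truth = simulate_cohort(seed=42)
assignment = cluster_samples(pdui)
ari = adjusted_rand_score(
    [truth.subgroup_of[s] for s in pdui.columns],
    [assignment.labels[s] for s in pdui.columns],
)
print(f"clustering: ARI vs planted subgroups = {ari:.3f}")
print("subgroup mean PDUI:", {k: round(v, 3) for k, v in assignment.mean_pdui.items()})

degs = differential_expression(expr, assignment)
n_up = (degs["direction"] == "up_in_C").sum()
n_down = (degs["direction"] == "down_in_C").sum()
print(f"DEG (C vs A): {n_up} up, {n_down} down")

candidates = intersect_genesets(degs, make_genesets(list(expr.index), truth, seed=42))
counts = apa_event_counts(pdui)
shortlist = correlation_screen(expr, counts, candidates)
final = overlap_core_factors(shortlist, truth.core_factors)
print(f"gene-set intersection: {len(candidates)} candidates")
print(f"correlation screen (|r|>0.3, p<0.05): {len(shortlist)} shortlisted")
print(
    f"key regulator: {final[0].gene_id} (r={final[0].pearson_r:.3f}); "
    f"planted: {truth.key_regulator}"
)
print(
    "An ARI of 1 means the three 3'UTR-length subgroups were recovered "
    "perfectly; the rank-1 core-factor overlap is the planted regulator."
)
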