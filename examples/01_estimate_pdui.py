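"""Estimate PDUI from two-isoform 3'UTR coverage.

Builds a 400-nt 3'UTR whose coverage is the superposition of a long
isoform (40 reads/base over the whole UTR) and a short isoform
(60 reads/base up to the proximal poly(A) site at offset 150), first
noise-free and then with Poisson count noise, and fits the breakpoint
model to each.
"""

from apakit import CoverageTruth, estimate_pdui, simulate_coverage

truth = CoverageTruth(
    gene_id="DEMO1", utr_length=400, proximal_site_true=150,
    depth_long=40.0, depth_short=60.0,
)
print(f"planted: PDUI={truth.pdui_true:.3f}, proximal site={truth.proximal_site_true}")

clean = estimate_pdui(simulate_coverage(truth))
print(
    f"noise-free fit: PDUI={clean.pdui:.3f}, site={clean.proximal_site}, "
    f"w_L={clean.long_abundance:.1f}, w_S={clean.short_abundance:.1f}, "
    f"SSE={clean.fit_sse:.2e}"
)

truth.noise_model, truth.seed = "poisson", 7
noisy = estimate_pdui(simulate_coverage(truth))
print(
    f"Poisson fit:    PDUI={noisy.pdui:.3f}, site={noisy.proximal_site}, "
    f"w_L={noisy.long_abundance:.1f}, w_S={noisy.short_abundance:.1f}"
)
print(
    "The noise-free fit recovers the planted values exactly; under count "
    "noise PDUI stays within a few hundredths and the site within a few nt."
)
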