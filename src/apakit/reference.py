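"""Reference brute-force two-isoform fit, used for validation.

Independent of the vectorized estimator in :mod:`apakit.pdui`: it loops
over every candidate breakpoint, solves the per-breakpoint non-negative
least squares in closed form, reconstructs the fitted profile, and
accumulates the residual sum of squares directly.  Intended for
cross-checks, not production use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BruteForceFit", "brute_force_pdui"]


@dataclass
class BruteForceFit:
    proximal_site: int
    long_abundance: float
    short_abundance: float
    pdui: float
    sse: float


def brute_force_pdui(depth: np.ndarray, end_margin: int) -> BruteForceFit:
    """Exhaustive breakpoint search with direct residual evaluation.

    Ties in SSE keep the earliest (most proximal) breakpoint, matching
    the production estimator's contract.
    """
    d = np.asarray(depth, dtype=float)
    L = d.size
    if 2 * end_margin >= L or end_margin < 1:
        raise ValueError("invalid end_margin for this profile length")
    x = np.arange(L)
    best: BruteForceFit | None = None
    for site in range(end_margin, L - end_margin):
        m1 = float(d[:site].mean())
        m2 = float(d[site:].mean())
        if m1 >= m2:
            w_s, w_l = m1 - m2, m2
        else:
            w_s, w_l = 0.0, float(d.mean())
        fit = np.where(x < site, w_s + w_l, w_l)
        sse = float(np.sum((d - fit) ** 2))
        if best is None or sse < best.sse:
            denom = w_l + w_s
            pdui = w_l / denom if denom > 0 else float("nan")
            best = BruteForceFit(site, w_l, w_s, pdui, sse)
    assert best is not None
    return best
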