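"""Two-isoform PDUI estimation from 3'UTR read coverage.

A gene with one proximal and one distal poly(A) site produces two mRNA
isoforms that differ only in 3'UTR length.  In transcript orientation
(offset 0 = 5' end of the 3'UTR) the expected per-base coverage is the
superposition of a long isoform spanning the whole UTR at ``w_L``
reads/base and a short isoform ending at the proximal site ``P`` at
``w_S`` reads/base::

    depth(x) = w_S + w_L   for x <  P
    depth(x) = w_L         for x >= P

For every candidate breakpoint the non-negative least-squares fit of
(w_S, w_L) has a closed form in the two segment means; the breakpoint
minimising the residual sum of squares is reported together with

    PDUI = w_L / (w_L + w_S)

the fraction of transcripts using the distal site (near 1 = long 3'UTR,
near 0 = short 3'UTR).  ``delta_pdui``/``test_apa_change`` compare PDUI
between a case and a control condition; ``apa_event_counts`` tallies
per-sample 3'UTR lengthening/shortening events in a cohort matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoverageProfile",
    "PDUIRecord",
    "APAChangeResult",
    "estimate_pdui",
    "delta_pdui",
    "test_apa_change",
    "apa_event_counts",
]

Call = Literal["lengthened", "shortened", "unchanged"]


@dataclass
class CoverageProfile:
    """Per-base read depth along one annotated 3'UTR.

    ``depth`` is indexed by transcript-orientation offset: position 0 is
    always the 3'UTR's 5' end, so minus-strand tracks must be reversed
    on load (see :func:`apakit.io.read_coverage`).  Genomic coordinates
    are 0-based half-open.
    """

    gene_id: str
    depth: np.ndarray
    chrom: str = "."
    strand: str = "+"
    utr_start: int = 0
    utr_end: int | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError(f"{self.gene_id}: depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError(f"{self.gene_id}: negative depth values")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.utr_end is None:
            self.utr_end = self.utr_start + self.depth.size
        if self.utr_end - self.utr_start != self.depth.size:
            raise ValueError(
                f"{self.gene_id}: interval length "
                f"{self.utr_end - self.utr_start} != depth length {self.depth.size}"
            )

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass
class PDUIRecord:
    """One gene/sample PDUI estimate.

    ``pdui`` is ``None`` when ``status == "low_coverage"``.  ``utr_length``
    travels with the record so pooled isoform read counts
    (abundance x length) can be reconstructed for significance testing.
    """

    gene_id: str
    sample_id: str = ""
    long_abundance: float = 0.0
    short_abundance: float = 0.0
    proximal_site: int | None = None
    pdui: float | None = None
    fit_sse: float = float("nan")
    status: Literal["ok", "low_coverage"] = "ok"
    utr_length: int = 0

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.pdui is None or not (0.0 <= self.pdui <= 1.0):
                raise ValueError(f"{self.gene_id}: pdui must be in [0,1] when status=ok")
            if self.long_abundance < 0 or self.short_abundance < 0:
                raise ValueError(f"{self.gene_id}: abundances must be non-negative")


@dataclass
class APAChangeResult:
    """Case-vs-control 3'UTR change for one gene (positive delta = lengthening)."""

    gene_id: str
    mean_pdui_case: float
    mean_pdui_control: float
    delta_pdui: float
    p_value: float | None
    call: Call

    def __post_init__(self) -> None:
        expected = self.mean_pdui_case - self.mean_pdui_control
        if not math.isclose(self.delta_pdui, expected, abs_tol=1e-9):
            raise ValueError(
                f"{self.gene_id}: delta_pdui {self.delta_pdui} != case-control {expected}"
            )


def estimate_pdui(
    profile: CoverageProfile,
    min_mean_depth: float = 5.0,
    end_margin: int = 50,
    sample_id: str = "",
) -> PDUIRecord:
    """Fit the two-isoform model over every candidate breakpoint.

    Every integer offset in ``[end_margin, L - end_margin)`` is tried;
    per breakpoint the non-negative least-squares solution is closed
    form (segment means, with w_S clamped to 0 when the distal mean
    exceeds the proximal mean).  Ties in SSE resolve to the most
    proximal (5'-most) breakpoint for determinism.

    Mean depth below ``min_mean_depth`` (or all-zero coverage) yields
    ``status="low_coverage"`` with ``pdui=None`` rather than an error:
    the estimate is unstable there.
    """
    d = profile.depth
    L = d.size
    if end_margin < 1:
        raise ValueError("end_margin must be >= 1")
    if 2 * end_margin >= L:
        raise ValueError(f"2*end_margin ({2 * end_margin}) must be < UTR length ({L})")

    if d.mean() < min_mean_depth or not np.any(d > 0):
        return PDUIRecord(
            gene_id=profile.gene_id,
            sample_id=sample_id,
            status="low_coverage",
            utr_length=L,
        )

    csum = np.concatenate(([0.0], np.cumsum(d)))
    total = csum[-1]
    sumsq = float(np.dot(d, d))
    bp = np.arange(end_margin, L - end_margin)
    n1 = bp.astype(float)
    n2 = float(L) - n1
    s1 = csum[bp]
    s2 = total - s1
    m1 = s1 / n1
    m2 = s2 / n2
    mu = total / L
    # SSE after projecting on the two-step basis; when m1 < m2 the NNLS
    # active set pins w_S = 0 and the fit collapses to the flat model.
    sse_step = sumsq - (s1 * s1 / n1 + s2 * s2 / n2)
    sse_flat = sumsq - L * mu * mu
    step_ok = m1 >= m2
    sse = np.where(step_ok, sse_step, sse_flat)

    i = int(np.argmin(sse))  # first minimum -> most proximal site
    site = int(bp[i])
    if step_ok[i]:
        w_l = float(m2[i])
        w_s = float(m1[i] - m2[i])
    else:
        w_l = float(mu)
        w_s = 0.0
    denom = w_l + w_s
    pdui = w_l / denom if denom > 0 else None
    if pdui is None:
        return PDUIRecord(
            gene_id=profile.gene_id,
            sample_id=sample_id,
            status="low_coverage",
            utr_length=L,
        )
    return PDUIRecord(
        gene_id=profile.gene_id,
        sample_id=sample_id,
        long_abundance=w_l,
        short_abundance=w_s,
        proximal_site=site,
        pdui=float(min(max(pdui, 0.0), 1.0)),
        fit_sse=float(max(sse[i], 0.0)),
        status="ok",
        utr_length=L,
    )


def _check_group(records: Sequence[PDUIRecord], label: str) -> str:
    if not records:
        raise ValueError(f"{label} group is empty")
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ValueError(f"{label} group mixes gene ids: {sorted(genes)}")
    for r in records:
        if r.status != "ok":
            raise ValueError(f"{label} group contains low_coverage records")
    return genes.pop()


def delta_pdui(
    case: Sequence[PDUIRecord], control: Sequence[PDUIRecord]
) -> APAChangeResult:
    """Mean PDUI difference, case minus control (positive = lengthening).

    Antisymmetric in argument order; no significance is attached (see
    :func:`test_apa_change`).
    """
    gene = _check_group(case, "case")
    gene_c = _check_group(control, "control")
    if gene != gene_c:
        raise ValueError(f"gene mismatch: case={gene} control={gene_c}")
    mc = float(np.mean([r.pdui for r in case]))
    mx = float(np.mean([r.pdui for r in control]))
    delta = mc - mx
    call: Call = "unchanged" if delta == 0 else ("lengthened" if delta > 0 else "shortened")
    return APAChangeResult(gene, mc, mx, delta, None, call)


def test_apa_change(
    case: Sequence[PDUIRecord],
    control: Sequence[PDUIRecord],
    alpha: float = 0.05,
    min_abs_delta: float = 0.05,
) -> APAChangeResult:
    """Fisher's exact test on pooled estimated isoform read counts.

    Per condition, long/short counts are ``round(abundance * UTR length)``
    summed over samples; the 2x2 table is tested two-sided.  A call of
    lengthened/shortened additionally requires |dPDUI| >= ``min_abs_delta``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    base = delta_pdui(case, control)

    def pooled(records: Sequence[PDUIRecord]) -> tuple[int, int]:
        long_n = int(round(sum(r.long_abundance * r.utr_length for r in records)))
        short_n = int(round(sum(r.short_abundance * r.utr_length for r in records)))
        return long_n, short_n

    cl, cs = pooled(case)
    xl, xs = pooled(control)
    if cl + cs == 0 or xl + xs == 0:
        return APAChangeResult(
            base.gene_id, base.mean_pdui_case, base.mean_pdui_control,
            base.delta_pdui, 1.0, "unchanged",
        )
    _, p = stats.fisher_exact([[cl, cs], [xl, xs]], alternative="two-sided")
    p = float(p)
    call: Call = "unchanged"
    if p < alpha and abs(base.delta_pdui) >= min_abs_delta:
        call = "lengthened" if base.delta_pdui > 0 else "shortened"
    return APAChangeResult(
        base.gene_id, base.mean_pdui_case, base.mean_pdui_control,
        base.delta_pdui, p, call,
    )


def apa_event_counts(
    pdui_matrix: pd.DataFrame,
    reference: Literal["cohort_median", "paired_normal"] = "cohort_median",
    event_threshold: float = 0.2,
    normal_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample counts of 3'UTR lengthening/shortening events.

    Gene g is lengthened in sample s iff PDUI(g,s) - reference(g) >=
    ``event_threshold`` (shortened symmetric).  The reference is the
    per-gene cohort median, or the paired normal sample's PDUI when
    ``reference="paired_normal"`` and ``normal_of`` maps each tumor
    sample to its normal column.  NA entries never count.

    Returns a DataFrame indexed by sample with columns ``n_lengthened``
    and ``n_shortened``.
    """
    if event_threshold <= 0:
        raise ValueError("event_threshold must be > 0")
    if pdui_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if reference == "cohort_median":
        ref = pdui_matrix.median(axis=1, skipna=True)
        diff = pdui_matrix.sub(ref, axis=0)
        samples = pdui_matrix.columns
    elif reference == "paired_normal":
        if not normal_of:
            raise ValueError("paired_normal reference requires normal_of pairing")
        samples = [s for s in pdui_matrix.columns if s in normal_of]
        missing = [s for s in samples if normal_of[s] not in pdui_matrix.columns]
        if missing:
            raise ValueError(f"normal columns missing for: {missing}")
        diff = pd.DataFrame(
            {s: pdui_matrix[s] - pdui_matrix[normal_of[s]] for s in samples}
        )
    else:
        raise ValueError(f"unknown reference {reference!r}")
    n_len = (diff >= event_threshold).sum(axis=0)
    n_short = (diff <= -event_threshold).sum(axis=0)
    return pd.DataFrame(
        {"n_lengthened": n_len.astype(int), "n_shortened": n_short.astype(int)},
        index=list(samples),
    )
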