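"""Three-criterion APA target funnel and qPCR quantitation utilities.

A gene is nominated as an APA target when it (1) carries at least two
PASs in its 3'UTR, (2) is upregulated in tumor, and (3) undergoes
significant 3'UTR lengthening upon regulator overexpression (raw
p < 0.001).  Criteria a gene cannot be evaluated on (missing from an
input) fail closed.  The module also provides the 2^-ddCT relative
quantitation transform and the long-transcript-to-total-transcript
ratio, whose semantics coincide with PDUI when the signals are isoform
abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .pas import PASClassification
from .pdui import APAChangeResult

__all__ = [
    "TargetRecord",
    "RatioMeasurement",
    "ALL_CRITERIA",
    "filter_targets",
    "long_to_total_ratio",
    "ddct_relative_expression",
]

ALL_CRITERIA = ("min_pas", "tumor_up", "lengthening")


@dataclass
class TargetRecord:
    """Per-gene funnel evaluation; ``passes`` holds one entry per
    criterion (None = unevaluable, which never selects)."""

    gene_id: str
    n_pas: int | None
    tumor_up: bool | None
    delta_pdui: float | None
    lengthening_p: float | None
    passes: dict[str, bool | None]
    selected: bool


@dataclass
class RatioMeasurement:
    gene_id: str
    long_signal: float
    total_signal: float
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"{self.gene_id}: ratio {self.ratio} outside [0,1]")


def filter_targets(
    pas_classifications: Iterable[PASClassification] | Mapping[str, int],
    deg_tumor_vs_normal: Mapping[str, bool],
    apa_change_results: Iterable[APAChangeResult],
    p_cutoff: float = 0.001,
    min_pas: int = 2,
    criteria: Sequence[str] = ALL_CRITERIA,
) -> list[TargetRecord]:
    """Evaluate every gene in the shared namespace against the funnel.

    ``pas_classifications`` is either full classifications or a plain
    gene -> PAS-count mapping; ``deg_tumor_vs_normal`` maps gene id ->
    upregulated-in-tumor flag.  ``criteria`` selects which of the three
    criteria must hold (the full conjunction by default); all three are
    always evaluated and recorded.  Output is sorted by ascending
    lengthening p-value (unevaluable last, ties by gene id), and is
    independent of input order.
    """
    unknown = set(criteria) - set(ALL_CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    if isinstance(pas_classifications, Mapping):
        pas_count = dict(pas_classifications)
    else:
        pas_count = {c.gene_id: c.n_pas for c in pas_classifications}
    change_by_gene = {r.gene_id: r for r in apa_change_results}
    genes = set(pas_count) | set(deg_tumor_vs_normal) | set(change_by_gene)

    records = []
    for gene in genes:
        n_pas = pas_count.get(gene)
        c_pas = (n_pas >= min_pas) if n_pas is not None else None

        up = deg_tumor_vs_normal.get(gene)
        c_up = bool(up) if up is not None else None

        change = change_by_gene.get(gene)
        if change is not None and change.p_value is not None:
            delta, p = change.delta_pdui, change.p_value
            c_len = change.call == "lengthened" and p < p_cutoff
        else:
            delta = p = None
            c_len = None

        passes = {"min_pas": c_pas, "tumor_up": c_up, "lengthening": c_len}
        selected = all(passes[c] is True for c in criteria)
        records.append(
            TargetRecord(
                gene_id=gene,
                n_pas=n_pas,
                tumor_up=c_up,
                delta_pdui=delta,
                lengthening_p=p,
                passes=passes,
                selected=selected,
            )
        )
    records.sort(
        key=lambda r: (
            r.lengthening_p if r.lengthening_p is not None else math.inf,
            r.gene_id,
        )
    )
    return records


def long_to_total_ratio(
    gene_id: str, long_signal: float, total_signal: float
) -> RatioMeasurement:
    """Long-transcript-to-total-transcript ratio (equals PDUI when the
    signals are isoform abundances).  A long signal exceeding the total
    by more than a 1e-9 relative tolerance is an error; smaller
    overshoots are clipped."""
    if total_signal <= 0:
        raise ValueError(f"{gene_id}: total_signal must be > 0")
    if long_signal < 0:
        raise ValueError(f"{gene_id}: long_signal must be >= 0")
    if long_signal > total_signal * (1 + 1e-9) + 1e-9:
        raise ValueError(
            f"{gene_id}: long_signal {long_signal} exceeds total_signal {total_signal}"
        )
    ratio = min(long_signal / total_signal, 1.0)
    return RatioMeasurement(gene_id, long_signal, total_signal, ratio)


def ddct_relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCT method:
    2^-[(Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl)]."""
    values = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
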