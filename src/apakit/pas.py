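"""Polyadenylation-signal (PAS) scanning and type a/b/c classification.

Cleavage/polyadenylation is directed by a hexamer signal: canonically
AATAAA (DNA alphabet), with a set of weaker non-canonical variants.
Genes are typed by the inventory of their *proximal* 3'UTR PASs:

* type a — proximal region holds only non-canonical signals,
* type b — proximal region holds both canonical and non-canonical,
* type c — proximal region holds only canonical signals,
* unclassified — no proximal signal (e.g. fewer than two sites total).

The proximal/distal split anchors on the 3'-most site: the distal PAS
defines the long-isoform end, and any signal within ``distal_window``
nucleotides of it is counted as part of the distal cluster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "CANONICAL_PAS",
    "DEFAULT_NONCANONICAL_PAS",
    "default_hexamer_set",
    "PASSite",
    "PASClassification",
    "scan_pas",
    "split_proximal_distal",
    "classify_gene",
    "classify_sequence",
    "proportion_proximal_noncanonical",
]

CANONICAL_PAS = "AATAAA"

# The 12 widely reported human variants (overridable everywhere).
DEFAULT_NONCANONICAL_PAS = (
    "ATTAAA", "TATAAA", "AGTAAA", "AATACA", "CATAAA", "AATATA",
    "GATAAA", "AATGAA", "AATAGA", "ACTAAA", "AAGAAA", "AATAAG",
)

PASType = Literal["a", "b", "c", "unclassified"]


def default_hexamer_set() -> frozenset[str]:
    return frozenset((CANONICAL_PAS, *DEFAULT_NONCANONICAL_PAS))


@dataclass(frozen=True)
class PASSite:
    """One PAS hexamer occurrence (0-based offset of its first base)."""

    offset: int
    hexamer: str
    canonical: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical", self.hexamer == CANONICAL_PAS)


@dataclass
class PASClassification:
    gene_id: str
    proximal_sites: list[PASSite]
    distal_sites: list[PASSite]
    pas_type: PASType

    @property
    def n_pas(self) -> int:
        return len(self.proximal_sites) + len(self.distal_sites)


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def scan_pas(sequence: str, hexamer_set: Iterable[str] | None = None) -> list[PASSite]:
    """Report every hexamer-set match in the sequence, overlaps included.

    Accepts A/C/G/T/N (and RNA U, mapped to T); N never matches.
    Sequences shorter than 6 nt yield an empty list.
    """
    seq = _normalize(sequence)
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    source = default_hexamer_set() if hexamer_set is None else hexamer_set
    hexamers = {_normalize(h) for h in source}
    if not hexamers:
        raise ValueError("hexamer_set is empty")
    if any(len(h) != 6 for h in hexamers):
        raise ValueError("all PAS motifs must be hexamers")
    if len(seq) < 6:
        return []
    pattern = re.compile("(?=(" + "|".join(map(re.escape, sorted(hexamers))) + "))")
    return [PASSite(m.start(), m.group(1)) for m in pattern.finditer(seq)]


def split_proximal_distal(
    sites: Sequence[PASSite],
    utr_length: int | None = None,
    distal_anchor: Literal["last_site", "annotated_distal"] = "last_site",
    distal_window: int = 50,
    annotated_distal: int | None = None,
) -> tuple[list[PASSite], list[PASSite]]:
    """Partition PAS sites into proximal and distal groups.

    The distal cluster is everything within ``distal_window`` nt of the
    anchor (the 3'-most site, or an annotated distal position).  Fewer
    than two sites cannot define a proximal region: all go distal and
    the gene stays unclassifiable.
    """
    if distal_window <= 0:
        raise ValueError("distal_window must be > 0")
    ordered = sorted(sites, key=lambda s: (s.offset, s.hexamer))
    if len(ordered) < 2:
        return [], list(ordered)
    if distal_anchor == "last_site":
        anchor = ordered[-1].offset
    elif distal_anchor == "annotated_distal":
        if annotated_distal is None:
            raise ValueError("annotated_distal anchor requires a position")
        anchor = annotated_distal
    else:
        raise ValueError(f"unknown distal_anchor {distal_anchor!r}")
    distal = [s for s in ordered if abs(anchor - s.offset) <= distal_window]
    proximal = [s for s in ordered if abs(anchor - s.offset) > distal_window]
    return proximal, distal


def classify_gene(
    gene_id: str,
    proximal_sites: Sequence[PASSite],
    distal_sites: Sequence[PASSite],
) -> PASClassification:
    """Assign type a/b/c from the proximal PAS inventory (duplicates and
    input order are irrelevant)."""
    prox = sorted(set(proximal_sites), key=lambda s: (s.offset, s.hexamer))
    dist = sorted(set(distal_sites), key=lambda s: (s.offset, s.hexamer))
    has_canon = any(s.canonical for s in prox)
    has_noncanon = any(not s.canonical for s in prox)
    if not prox:
        pas_type: PASType = "unclassified"
    elif has_canon and has_noncanon:
        pas_type = "b"
    elif has_noncanon:
        pas_type = "a"
    else:
        pas_type = "c"
    return PASClassification(gene_id, prox, dist, pas_type)


def classify_sequence(
    gene_id: str,
    sequence: str,
    hexamer_set: Iterable[str] | None = None,
    distal_window: int = 50,
) -> PASClassification:
    """Scan, split, and type one 3'UTR sequence in a single call."""
    sites = scan_pas(sequence, hexamer_set)
    proximal, distal = split_proximal_distal(
        sites, utr_length=len(sequence), distal_window=distal_window
    )
    return classify_gene(gene_id, proximal, distal)


def proportion_proximal_noncanonical(
    classifications: Iterable[PASClassification],
) -> float:
    """Fraction of classified genes carrying a proximal non-canonical PAS:
    (#a + #b) / (#a + #b + #c).  NaN when no gene is classifiable."""
    counts = {"a": 0, "b": 0, "c": 0}
    for c in classifications:
        if c.pas_type in counts:
            counts[c.pas_type] += 1
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return (counts["a"] + counts["b"]) / total
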