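"""Synthetic ground-truth generators for every pipeline input.

Three generators stand in for the cohort and cell-line data the pipeline
normally consumes, each emitting its planted truth alongside the data:

* :func:`simulate_coverage` — step-shaped two-isoform 3'UTR coverage
  with known PDUI and proximal-site position, optionally with Poisson
  per-base count noise.
* :func:`simulate_cohort` — a gene x sample PDUI matrix with three
  planted subgroups of differing mean 3'UTR length, plus an expression
  matrix in which planted regulator genes track each sample's burden of
  3'UTR lengthening/shortening events.
* :func:`simulate_utr_sequences` — 3'UTR sequences with planted
  canonical/non-canonical PAS hexamers realizing types a/b/c on a
  background scrubbed of accidental signals.
* :func:`simulate_funnel_inputs` — per-gene PAS inventories, tumor
  expression direction and APA-change calls with an exact planted set
  of genes satisfying all three target-funnel criteria.

All randomness flows from one explicit integer seed per call; there is
no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pas import (
    CANONICAL_PAS,
    PASClassification,
    PASSite,
    classify_gene,
    default_hexamer_set,
    scan_pas,
    split_proximal_distal,
)
from .pdui import APAChangeResult, CoverageProfile

__all__ = [
    "CoverageTruth",
    "CohortEffects",
    "CohortTruth",
    "SequenceTruth",
    "FunnelInputs",
    "FunnelTruth",
    "simulate_coverage",
    "simulate_cohort",
    "make_genesets",
    "simulate_utr_sequences",
    "simulate_funnel_inputs",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageTruth:
    """Generative parameters of one two-isoform coverage profile."""

    gene_id: str
    utr_length: int
    proximal_site_true: int
    depth_long: float
    depth_short: float
    noise_model: Literal["none", "poisson"] = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.utr_length <= 0:
            raise ValueError("utr_length must be positive")
        if not 0 < self.proximal_site_true < self.utr_length:
            raise ValueError("proximal_site_true must lie strictly inside the UTR")
        if self.depth_long < 0 or self.depth_short < 0:
            raise ValueError("expected depths must be non-negative")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0.0 <= self.pdui_true <= 1.0:
            raise ValueError("pdui_true outside [0,1]")

    @property
    def pdui_true(self) -> float:
        total = self.depth_long + self.depth_short
        return self.depth_long / total if total > 0 else float("nan")

    @classmethod
    def from_pdui(
        cls,
        gene_id: str,
        utr_length: int,
        proximal_site_true: int,
        total_depth: float,
        pdui_true: float,
        noise_model: Literal["none", "poisson"] = "none",
        seed: int = 0,
    ) -> "CoverageTruth":
        if not 0.0 <= pdui_true <= 1.0:
            raise ValueError("pdui_true outside [0,1]")
        return cls(
            gene_id=gene_id,
            utr_length=utr_length,
            proximal_site_true=proximal_site_true,
            depth_long=total_depth * pdui_true,
            depth_short=total_depth * (1.0 - pdui_true),
            noise_model=noise_model,
            seed=seed,
        )


def simulate_coverage(truth: CoverageTruth) -> CoverageProfile:
    """Expected depth is depth_long + depth_short before the proximal
    site and depth_long after it; Poisson noise draws per-base counts
    with those means, reproducibly under the truth's seed."""
    expected = np.where(
        np.arange(truth.utr_length) < truth.proximal_site_true,
        truth.depth_long + truth.depth_short,
        truth.depth_long,
    ).astype(float)
    if truth.noise_model == "poisson":
        rng = np.random.default_rng(truth.seed)
        depth = rng.poisson(expected).astype(float)
    else:
        depth = expected
    return CoverageProfile(gene_id=truth.gene_id, depth=depth)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortEffects:
    """Effect sizes of the cohort generator (the study conditions).

    ``subgroup_shift`` is the mean PDUI gap between subgroups A and C;
    ``regulator_effect`` the target raw-scale Pearson correlation
    between regulator expression and its matched event-count series;
    event rates are events/sample, with the subgroup spread carrying the
    lengthening-in-A / shortening-in-C contrast.  ``null()`` zeroes all
    planted signal so no downstream statistic can separate subgroups
    beyond chance.
    """

    subgroup_shift: float = 0.25
    regulator_effect: float = 0.6
    event_magnitude: float = 0.35
    event_rate_base: float = 25.0
    event_rate_spread: float = 15.0
    event_rate_sd: float = 4.0
    pdui_noise_sd: float = 0.02
    baseline_pdui_low: float = 0.35
    baseline_pdui_high: float = 0.65
    expression_log2_gain: float = 0.8
    background_log2_mean: float = 6.6
    background_log2_sd: float = 0.5
    deg_log2fc: float = 2.5
    n_lengthen_regulators: int = 2
    n_shorten_regulators: int = 2
    n_planted_degs: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.subgroup_shift < 1.0:
            raise ValueError("subgroup_shift must be in [0,1)")
        if not 0.0 <= self.regulator_effect <= 1.0:
            raise ValueError("regulator_effect must be in [0,1]")
        if self.event_magnitude < 0 or self.pdui_noise_sd < 0:
            raise ValueError("event_magnitude and pdui_noise_sd must be >= 0")
        if self.event_rate_base < 0 or self.event_rate_spread < 0:
            raise ValueError("event rates must be >= 0")
        if self.event_rate_spread > self.event_rate_base:
            raise ValueError("event_rate_spread cannot exceed event_rate_base")
        if not 0.0 <= self.baseline_pdui_low <= self.baseline_pdui_high <= 1.0:
            raise ValueError("baseline PDUI range must satisfy 0 <= low <= high <= 1")

    @classmethod
    def null(cls) -> "CohortEffects":
        """Label-free configuration: no subgroup, regulator or DEG signal."""
        return cls(
            subgroup_shift=0.0,
            regulator_effect=0.0,
            event_rate_spread=0.0,
            deg_log2fc=0.0,
        )


@dataclass
class CohortTruth:
    """Planted ground truth of one simulated cohort."""

    subgroup_of: dict[str, str]
    lengthening_regulators: set[str]
    shortening_regulators: set[str]
    regulator_effect: float
    apa_event_genes: dict[str, dict[str, set[str]]]
    tumor_label: dict[str, str]
    key_regulator: str | None
    core_factors: list[str]
    deg_up_in_C: set[str]
    deg_down_in_C: set[str]

    def __post_init__(self) -> None:
        if self.lengthening_regulators & self.shortening_regulators:
            raise ValueError("regulator sets must be disjoint")
        groups = set(self.subgroup_of.values())
        if not groups:
            raise ValueError("no samples")

    def event_counts(self) -> pd.DataFrame:
        """Planted per-sample event counts (same shape as apa_event_counts)."""
        rows = {
            s: {
                "n_lengthened": len(d["lengthened"]),
                "n_shortened": len(d["shortened"]),
            }
            for s, d in self.apa_event_genes.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").astype(int)


def _regulator_log2_noise_sd(gain: float, target_r: float) -> float:
    """Log2-scale noise sd making the raw-scale Pearson correlation of a
    log-normal expression series with its (standardized) driver equal
    ``target_r``; clipped to 0 when the target saturates."""
    ap = gain * math.log(2.0)
    s2 = math.log1p((ap / target_r) ** 2)
    return math.sqrt(max(s2 - ap * ap, 0.0)) / math.log(2.0)


def simulate_cohort(
    n_genes: int = 500,
    n_samples: int = 60,
    subgroup_sizes: tuple[int, int, int] = (20, 20, 20),
    effects: CohortEffects | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a PDUI matrix, an expression matrix and their truth.

    Subgroup A gets the positive half of ``subgroup_shift``, C the
    negative half (B centred); each sample additionally receives a
    planted set of lengthening/shortening events (PDUI moved by
    ``event_magnitude``, detectable against the cohort median), with
    lengthening events enriched in A and shortening in C.  Regulator
    expression is log-normal and driven by the realized event counts so
    its raw-scale correlation targets ``regulator_effect``.  All PDUI
    entries lie in [0,1]; output is deterministic under ``seed``.
    """
    if n_genes <= 0 or n_samples <= 0:
        raise ValueError("n_genes and n_samples must be positive")
    if len(subgroup_sizes) != 3 or any(s <= 0 for s in subgroup_sizes):
        raise ValueError("subgroup_sizes must be 3 positive counts")
    if sum(subgroup_sizes) != n_samples:
        raise ValueError("subgroup sizes must sum to n_samples")
    eff = effects if effects is not None else CohortEffects()
    rng = np.random.default_rng(seed)

    samples = [f"S{i:03d}" for i in range(n_samples)]
    subgroup = (
        ["A"] * subgroup_sizes[0] + ["B"] * subgroup_sizes[1] + ["C"] * subgroup_sizes[2]
    )
    genes = [f"G{i:04d}" for i in range(n_genes)]
    n_l, n_s = eff.n_lengthen_regulators, eff.n_shorten_regulators
    n_d = eff.n_planted_degs
    reserved = n_l + n_s + n_d + 3
    if reserved >= n_genes:
        raise ValueError("n_genes too small for the requested planted genes")
    lengthen_regs = genes[:n_l]
    shorten_regs = genes[n_l : n_l + n_s]
    deg_up = genes[n_l + n_s : n_l + n_s + n_d // 2]
    deg_down = genes[n_l + n_s + n_d // 2 : n_l + n_s + n_d]
    core_fillers = genes[-3:]
    pool = genes[n_l + n_s + n_d : n_genes - 3]
    pool_idx = np.arange(n_l + n_s + n_d, n_genes - 3)

    offset_of = {"A": eff.subgroup_shift / 2, "B": 0.0, "C": -eff.subgroup_shift / 2}
    mu = rng.uniform(eff.baseline_pdui_low, eff.baseline_pdui_high, n_genes)
    pdui = np.tile(mu[:, None], (1, n_samples))
    pdui += np.array([offset_of[g] for g in subgroup])[None, :]
    if eff.pdui_noise_sd > 0:
        pdui += rng.normal(0.0, eff.pdui_noise_sd, pdui.shape)

    spread_of = {"A": 1.0, "B": 0.0, "C": -1.0}
    n_len = np.zeros(n_samples, dtype=int)
    n_short = np.zeros(n_samples, dtype=int)
    apa_event_genes: dict[str, dict[str, set[str]]] = {}
    cap = len(pool_idx) // 2
    for j, s in enumerate(samples):
        d = spread_of[subgroup[j]]
        lam_len = eff.event_rate_base + eff.event_rate_spread * d
        lam_short = eff.event_rate_base - eff.event_rate_spread * d
        k_len = int(np.clip(round(rng.normal(lam_len, eff.event_rate_sd)), 0, cap))
        k_short = int(np.clip(round(rng.normal(lam_short, eff.event_rate_sd)), 0, cap))
        chosen = rng.choice(pool_idx, size=k_len + k_short, replace=False)
        li, si = chosen[:k_len], chosen[k_len:]
        pdui[li, j] += eff.event_magnitude
        pdui[si, j] -= eff.event_magnitude
        n_len[j], n_short[j] = k_len, k_short
        apa_event_genes[s] = {
            "lengthened": {genes[i] for i in li},
            "shortened": {genes[i] for i in si},
        }
    pdui = np.clip(pdui, 0.0, 1.0)

    log2e = rng.normal(eff.background_log2_mean, eff.background_log2_sd, (n_genes, n_samples))
    dirvec = np.array([{"A": -0.5, "B": 0.0, "C": 0.5}[g] for g in subgroup])
    for g in deg_up:
        log2e[genes.index(g)] += eff.deg_log2fc * dirvec
    for g in deg_down:
        log2e[genes.index(g)] -= eff.deg_log2fc * dirvec
    if eff.regulator_effect > 0:
        gain = eff.expression_log2_gain
        noise_sd = _regulator_log2_noise_sd(gain, eff.regulator_effect)
        for g, counts in [(g, n_len) for g in lengthen_regs] + [
            (g, n_short) for g in shorten_regs
        ]:
            sd = counts.std()
            z = (counts - counts.mean()) / sd if sd > 0 else np.zeros(n_samples)
            log2e[genes.index(g)] = (
                eff.background_log2_mean
                + gain * z
                + noise_sd * rng.normal(0.0, 1.0, n_samples)
            )
    expr = np.power(2.0, log2e)

    key = lengthen_regs[0] if lengthen_regs else (shorten_regs[0] if shorten_regs else None)
    truth = CohortTruth(
        subgroup_of=dict(zip(samples, subgroup)),
        lengthening_regulators=set(lengthen_regs),
        shortening_regulators=set(shorten_regs),
        regulator_effect=eff.regulator_effect,
        apa_event_genes=apa_event_genes,
        tumor_label={s: "tumor" for s in samples},
        key_regulator=key,
        core_factors=([key] if key else []) + core_fillers,
        deg_up_in_C=set(deg_up),
        deg_down_in_C=set(deg_down),
    )
    pdui_df = pd.DataFrame(pdui, index=genes, columns=samples)
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    return pdui_df, expr_df, truth


def make_genesets(
    genes: Sequence[str],
    truth: CohortTruth,
    n_extra: int = 60,
    seed: int = 0,
) -> dict[str, set[str]]:
    """APA-related gene sets containing every planted regulator plus
    random non-regulator members (mimicking mRNA-processing / RNA-binding /
    nucleus GO sets; membership downstream is the union)."""
    rng = np.random.default_rng(seed)
    regulators = sorted(truth.lengthening_regulators | truth.shortening_regulators)
    planted_degs = truth.deg_up_in_C | truth.deg_down_in_C
    background = [g for g in genes if g not in set(regulators) and g not in planted_degs]
    sets: dict[str, set[str]] = {}
    for name in ("mRNA_processing", "RNA_binding", "nucleus"):
        extras = rng.choice(background, size=min(n_extra, len(background)), replace=False)
        members = set(extras)
        if name == "RNA_binding":
            members |= set(regulators)
        else:
            members |= set(regulators[: max(1, len(regulators) // 2)])
        sets[name] = members
    return sets


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class SequenceTruth:
    """One generated 3'UTR with its planted PAS inventory."""

    gene_id: str
    utr_sequence: str
    planted_proximal_hexamers: list[tuple[int, str]]
    planted_distal_hexamers: list[tuple[int, str]]
    type_true: Literal["a", "b", "c"]

    def __post_init__(self) -> None:
        for off, hexamer in self.planted_proximal_hexamers + self.planted_distal_hexamers:
            if self.utr_sequence[off : off + 6] != hexamer:
                raise ValueError(f"{self.gene_id}: hexamer not findable at offset {off}")


def _scrub_accidental_hits(
    seq: np.ndarray,
    hexamers: set[str],
    planted_offsets: set[int],
    protected: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 500,
) -> None:
    """Mutate bases in place until the only hexamer-set matches are the
    planted ones; never touches protected positions.

    Position and replacement base are drawn at random each round: in
    contexts like ``AATA_A`` every substitution at one position still
    spells a PAS variant, so a fixed choice could never converge.
    """
    for _ in range(max_rounds):
        hits = [s.offset for s in scan_pas("".join(seq), hexamers)]
        accidental = [o for o in hits if o not in planted_offsets]
        if not accidental:
            return
        off = accidental[0]
        candidates = [p for p in range(off, off + 6) if not protected[p]]
        if not candidates:  # fully inside planted windows; cannot happen with spacing
            raise RuntimeError("accidental PAS overlaps planted sites entirely")
        p = int(rng.choice(candidates))
        current = seq[p]
        seq[p] = rng.choice(_BASES[_BASES != current])
    raise RuntimeError("failed to scrub accidental PAS hexamers")


def simulate_utr_sequences(
    n_per_type: int | tuple[int, int, int],
    hexamer_set: Iterable[str] | None = None,
    seed: int = 0,
    utr_length: int = 600,
    distal_window: int = 50,
) -> list[SequenceTruth]:
    """Generate 3'UTRs realizing types a/b/c with exact planted truth.

    Backgrounds are uniform ACGT with accidental hexamer-set matches
    rejection-scrubbed, so a full-sequence scan finds exactly the
    planted sites.  Every gene carries one distal canonical PAS (the
    long-isoform end) plus the type-defining proximal inventory.
    ``n_per_type`` is either one count for each of a/b/c or a triple.
    """
    counts = (
        (n_per_type,) * 3 if isinstance(n_per_type, int) else tuple(n_per_type)
    )
    if len(counts) != 3 or any(c < 0 for c in counts) or sum(counts) < 1:
        raise ValueError("n_per_type must be a positive count or triple of counts")
    hexamers = {h.upper().replace("U", "T") for h in (hexamer_set or default_hexamer_set())}
    if CANONICAL_PAS not in hexamers:
        raise ValueError(f"hexamer_set must contain the canonical PAS {CANONICAL_PAS}")
    noncanonical = sorted(hexamers - {CANONICAL_PAS})
    if not noncanonical and (counts[0] > 0 or counts[1] > 0):
        raise ValueError("types a and b require at least one non-canonical hexamer")
    if utr_length < 250:
        raise ValueError("utr_length must be >= 250 to separate proximal and distal")

    rng = np.random.default_rng(seed)
    out: list[SequenceTruth] = []
    distal_off = utr_length - 80
    prox_lo, prox_hi = 40, distal_off - distal_window - 30
    for type_label, n in zip("abc", counts):
        for i in range(n):
            if type_label == "a":
                prox_hex = [str(rng.choice(noncanonical))]
            elif type_label == "b":
                prox_hex = [CANONICAL_PAS, str(rng.choice(noncanonical))]
            else:
                prox_hex = [CANONICAL_PAS]
            while True:
                offsets = np.sort(
                    rng.choice(np.arange(prox_lo, prox_hi), size=len(prox_hex), replace=False)
                )
                if len(offsets) < 2 or np.min(np.diff(offsets)) >= 12:
                    break
            order = rng.permutation(len(prox_hex))
            planted = [(int(offsets[k]), prox_hex[order[k]]) for k in range(len(prox_hex))]
            planted_distal = [(distal_off, CANONICAL_PAS)]

            seq = rng.choice(_BASES, size=utr_length)
            protected = np.zeros(utr_length, dtype=bool)
            for off, hexamer in planted + planted_distal:
                seq[off : off + 6] = list(hexamer)
                protected[off : off + 6] = True
            _scrub_accidental_hits(
                seq, hexamers, {off for off, _ in planted + planted_distal}, protected, rng
            )
            out.append(
                SequenceTruth(
                    gene_id=f"UTR{type_label}{i:04d}",
                    utr_sequence="".join(seq),
                    planted_proximal_hexamers=planted,
                    planted_distal_hexamers=planted_distal,
                    type_true=type_label,  # type: ignore[arg-type]
                )
            )
    return out


# ---------------------------------------------------------------------------
# funnel
# ---------------------------------------------------------------------------


@dataclass
class FunnelTruth:
    selected: set[str]
    flags: dict[str, tuple[bool, bool, bool]]  # (>=2 PAS, tumor-up, lengthening)


@dataclass
class FunnelInputs:
    classifications: list[PASClassification]
    tumor_up: dict[str, bool]
    apa_changes: list[APAChangeResult]
    truth: FunnelTruth


_FAIL_PATTERNS = [
    (False, True, True),
    (True, False, True),
    (True, True, False),
    (False, False, True),
    (False, True, False),
    (True, False, False),
    (False, False, False),
]


def simulate_funnel_inputs(
    n_genes: int = 500,
    n_selected: int = 47,
    seed: int = 0,
    utr_length: int = 1000,
    distal_window: int = 50,
) -> FunnelInputs:
    """Per-gene funnel inputs with an exact planted selected set.

    Exactly ``n_selected`` genes satisfy all three criteria (>= 2 PAS,
    up in tumor, significant lengthening at p < 0.001); the remainder
    cycle through every failure pattern, so each single criterion
    excludes at least one gene that passes the other two.
    """
    if not 0 <= n_selected <= n_genes:
        raise ValueError("n_selected must be between 0 and n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"T{i:04d}" for i in range(n_genes)]
    chosen = set(rng.choice(genes, size=n_selected, replace=False))

    classifications: list[PASClassification] = []
    tumor_up: dict[str, bool] = {}
    changes: list[APAChangeResult] = []
    flags: dict[str, tuple[bool, bool, bool]] = {}
    fail_i = 0
    for g in genes:
        if g in chosen:
            c1, c2, c3 = True, True, True
        else:
            c1, c2, c3 = _FAIL_PATTERNS[fail_i % len(_FAIL_PATTERNS)]
            fail_i += 1
        flags[g] = (c1, c2, c3)

        distal = PASSite(utr_length - 60, CANONICAL_PAS)
        if c1:
            prox_hex = str(
                rng.choice([CANONICAL_PAS, "ATTAAA", "TATAAA", "AGTAAA"])
            )
            sites = [PASSite(int(rng.integers(50, 400)), prox_hex), distal]
        else:
            sites = [distal]
        proximal, dist = split_proximal_distal(
            sites, utr_length=utr_length, distal_window=distal_window
        )
        classifications.append(classify_gene(g, proximal, dist))
        tumor_up[g] = bool(c2)
        if c3:
            p = float(rng.uniform(1e-6, 9e-4))
            mc, mx = 0.75, 0.40
            call = "lengthened"
        else:
            mode = int(rng.integers(3))
            if mode == 0:  # lengthened but not at the stringent cutoff
                p, mc, mx, call = float(rng.uniform(2e-3, 4e-2)), 0.62, 0.50, "lengthened"
            elif mode == 1:
                p, mc, mx, call = float(rng.uniform(1e-6, 1e-3)), 0.35, 0.70, "shortened"
            else:
                p, mc, mx, call = float(rng.uniform(0.1, 0.9)), 0.55, 0.54, "unchanged"
        changes.append(
            APAChangeResult(g, mc, mx, mc - mx, p, call)  # type: ignore[arg-type]
        )
    return FunnelInputs(
        classifications=classifications,
        tumor_up=tumor_up,
        apa_changes=changes,
        truth=FunnelTruth(selected=chosen, flags=flags),
    )
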