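"""Cohort APA landscape: PDUI clustering and the APA-regulator screen.

Samples are clustered hierarchically on their gene x sample PDUI matrix
into k subgroups, relabeled A/B/C by descending mean PDUI (A = longest
3'UTRs).  Candidate regulators are then funneled through four stages:

1. differential expression between the extreme subgroups (C vs A),
2. intersection with APA-related gene sets (union membership),
3. Pearson correlation of expression with the per-sample count of
   3'UTR lengthening/shortening events (keep |r| > 0.3, p < 0.05),
4. overlap with the known core APA machinery, ranked by |r|.

Down-in-C genes are potential 3'UTR-lengthen regulators (their loss
accompanies shortening); up-in-C genes are potential shorten regulators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from string import ascii_uppercase
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupAssignment",
    "DEGResult",
    "RegulatorCandidate",
    "cluster_samples",
    "differential_expression",
    "intersect_genesets",
    "correlation_screen",
    "overlap_core_factors",
]

Role = Literal["lengthen_regulator", "shorten_regulator"]


@dataclass
class SubgroupAssignment:
    """Sample -> subgroup label; A has the highest mean PDUI, C the lowest."""

    labels: pd.Series
    mean_pdui: dict[str, float]

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def __post_init__(self) -> None:
        groups = sorted(self.labels.unique())
        means = [self.mean_pdui[g] for g in groups]
        if any(a < b for a, b in zip(means, means[1:])):
            raise ValueError("labels must be ordered by descending mean PDUI")


@dataclass
class DEGResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    fdr: float
    direction: Literal["up_in_C", "down_in_C", "ns"]


@dataclass
class RegulatorCandidate:
    gene_id: str
    role: Role
    pearson_r: float | None = None
    p_value: float | None = None
    in_geneset: bool = False
    is_core_factor: bool = False


def _pairwise_complete_euclidean(x: np.ndarray) -> np.ndarray:
    """Euclidean distance between sample columns, pairwise-complete over
    NA entries and rescaled to the full gene count."""
    valid = ~np.isnan(x)
    xz = np.where(valid, x, 0.0)
    sq = xz**2
    v = valid.astype(float)
    n_pairs = v.T @ v
    d2 = sq.T @ v + v.T @ sq - 2.0 * (xz.T @ xz)
    if np.any(n_pairs == 0):
        raise ValueError("some sample pairs share no observed genes")
    d2 = np.maximum(d2, 0.0) * (x.shape[0] / n_pairs)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def cluster_samples(
    pdui_matrix: pd.DataFrame,
    k: int = 3,
    linkage: str = "average",
    max_na_fraction: float = 0.2,
) -> SubgroupAssignment:
    """Agglomerative clustering of samples on PDUI, cut at k groups.

    Genes with >= ``max_na_fraction`` missing values are dropped;
    distances are pairwise-complete Euclidean.  Degenerate inputs where
    samples are indistinguishable (or the tree yields fewer than k
    groups) fall back to a deterministic contiguous split with a loud
    warning rather than crashing.
    """
    if pdui_matrix.shape[1] < k:
        raise ValueError(f"need at least k={k} samples, got {pdui_matrix.shape[1]}")
    vals = pdui_matrix.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("all-NA PDUI matrix")
    if finite.min() < 0 or finite.max() > 1:
        raise ValueError("PDUI entries must lie in [0,1] (or NA)")

    na_frac = pdui_matrix.isna().mean(axis=1)
    kept = pdui_matrix.loc[na_frac < max_na_fraction]
    if kept.empty:
        raise ValueError("no gene passes the NA-fraction filter")
    dist = _pairwise_complete_euclidean(kept.to_numpy(dtype=float))

    samples = list(pdui_matrix.columns)
    if np.allclose(dist, 0.0):
        warnings.warn(
            "samples are indistinguishable on PDUI; using a deterministic "
            "contiguous split",
            stacklevel=2,
        )
        cluster_ids = np.array([i * k // len(samples) for i in range(len(samples))])
    else:
        z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        cluster_ids = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(cluster_ids)) < k:
            warnings.warn(
                f"tree cut produced fewer than k={k} groups; using a "
                "deterministic contiguous split",
                stacklevel=2,
            )
            cluster_ids = np.array([i * k // len(samples) for i in range(len(samples))])

    labels_raw = pd.Series(cluster_ids, index=samples)
    sample_means = pdui_matrix.mean(axis=0, skipna=True)
    group_means = sample_means.groupby(labels_raw).mean()
    order = group_means.sort_values(ascending=False, kind="stable").index
    rename = {raw: ascii_uppercase[i] for i, raw in enumerate(order)}
    labels = labels_raw.map(rename)
    mean_pdui = {rename[raw]: float(group_means[raw]) for raw in order}
    return SubgroupAssignment(labels=labels, mean_pdui=mean_pdui)


def differential_expression(
    expr_matrix: pd.DataFrame,
    groups: SubgroupAssignment,
    contrast: tuple[str, str] = ("C", "A"),
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum between two subgroups with BH-FDR.

    The test runs on log2(expr+1); the reported fold change is the
    ratio of raw group means (pseudocount 1 only when a mean is zero).
    Returns a DataFrame indexed by gene with columns
    ``log2_fold_change``, ``p_value``, ``fdr``, ``direction``
    (direction names refer to the first contrast group).
    """
    g1, g0 = contrast
    cols1 = [s for s in groups.samples(g1) if s in expr_matrix.columns]
    cols0 = [s for s in groups.samples(g0) if s in expr_matrix.columns]
    if len(cols1) < 3 or len(cols0) < 3:
        raise ValueError("both contrast groups need at least 3 samples")
    x1 = np.log2(expr_matrix[cols1].to_numpy(dtype=float) + 1.0)
    x0 = np.log2(expr_matrix[cols0].to_numpy(dtype=float) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(x1, x0, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    pooled = np.concatenate([x1, x0], axis=1)
    constant = np.ptp(pooled, axis=1) == 0
    p = np.where(constant | ~np.isfinite(p), 1.0, p)

    m1 = expr_matrix[cols1].mean(axis=1).to_numpy(dtype=float)
    m0 = expr_matrix[cols0].mean(axis=1).to_numpy(dtype=float)
    zero = (m1 <= 0) | (m0 <= 0)
    lfc = np.where(
        zero,
        np.log2(m1 + 1.0) - np.log2(m0 + 1.0),
        np.log2(np.where(zero, 1.0, m1)) - np.log2(np.where(zero, 1.0, m0)),
    )
    fdr = multipletests(p, method="fdr_bh")[1]
    sig = (fdr < fdr_threshold) & (np.abs(lfc) > lfc_threshold)
    direction = np.where(
        sig & (lfc > 0), f"up_in_{g1}", np.where(sig & (lfc < 0), f"down_in_{g1}", "ns")
    )
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=expr_matrix.index,
    )


def intersect_genesets(
    degs: pd.DataFrame, genesets: Mapping[str, set[str]]
) -> list[RegulatorCandidate]:
    """Keep directional DEGs present in at least one gene set (union
    semantics): down-in-C -> lengthen regulator, up-in-C -> shorten."""
    if not genesets or all(len(s) == 0 for s in genesets.values()):
        raise ValueError("genesets are empty")
    union: set[str] = set().union(*genesets.values())
    directional = degs[degs["direction"] != "ns"]
    if len(directional) and not (set(degs.index) & union):
        logger.warning(
            "no overlap between DEG gene ids and gene-set ids: "
            "possible identifier namespace mismatch"
        )
    unmatched = len(directional) - directional.index.isin(union).sum()
    if unmatched:
        logger.info("%d directional DEGs not found in any gene set", unmatched)
    out: list[RegulatorCandidate] = []
    for gene in sorted(directional.index):
        if gene not in union:
            continue
        direction = directional.loc[gene, "direction"]
        role: Role = "lengthen_regulator" if direction.startswith("down") else "shorten_regulator"
        out.append(RegulatorCandidate(gene_id=gene, role=role, in_geneset=True))
    return out


def correlation_screen(
    expr_matrix: pd.DataFrame,
    apa_counts: pd.DataFrame,
    candidates: Sequence[RegulatorCandidate],
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> list[RegulatorCandidate]:
    """Pearson correlation of candidate expression with the role-matched
    per-sample event counts; shortlist |r| > r_threshold, p < p_threshold.

    Zero-variance expression rows are excluded with a warning (r is
    undefined there).
    """
    common = [s for s in expr_matrix.columns if s in apa_counts.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    shortlisted: list[RegulatorCandidate] = []
    for cand in candidates:
        if cand.gene_id not in expr_matrix.index:
            raise ValueError(f"candidate {cand.gene_id} missing from expression matrix")
        expr = expr_matrix.loc[cand.gene_id, common].to_numpy(dtype=float)
        series = (
            "n_lengthened" if cand.role == "lengthen_regulator" else "n_shortened"
        )
        counts = apa_counts.loc[common, series].to_numpy(dtype=float)
        if np.ptp(expr) == 0 or np.ptp(counts) == 0:
            warnings.warn(
                f"{cand.gene_id}: zero-variance series, correlation undefined; excluded",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(expr, counts)
        cand.pearson_r = float(r)
        cand.p_value = float(p)
        if abs(r) > r_threshold and p < p_threshold:
            shortlisted.append(cand)
    return shortlisted


def overlap_core_factors(
    shortlist: Sequence[RegulatorCandidate], core_factor_list: Iterable[str]
) -> list[RegulatorCandidate]:
    """Intersect the shortlist with the core APA machinery, ranked by
    descending |r| (ties broken by gene id); rank 1 is the key regulator."""
    core = set(core_factor_list)
    if not core:
        raise ValueError("core factor list is empty")
    hits = [c for c in shortlist if c.gene_id in core]
    for c in hits:
        c.is_core_factor = True
    return sorted(hits, key=lambda c: (-abs(c.pearson_r or 0.0), c.gene_id))
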