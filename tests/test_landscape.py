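"""Tests for PDUI clustering and the APA-regulator screen."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from apakit import (
    RegulatorCandidate,
    cluster_samples,
    correlation_screen,
    differential_expression,
    intersect_genesets,
    overlap_core_factors,
)


def block_matrix(levels=(0.9, 0.6, 0.3), per_group=5, n_genes=40, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cols, data, truth = [], [], []
    for gi, level in enumerate(levels):
        for s in range(per_group):
            cols.append(f"g{gi}s{s}")
            col = np.full(n_genes, level)
            if jitter:
                col = np.clip(col + rng.normal(0, jitter, n_genes), 0, 1)
            data.append(col)
            truth.append(gi)
    df = pd.DataFrame(
        np.column_stack(data), index=[f"G{i}" for i in range(n_genes)], columns=cols
    )
    return df, truth


class TestClusterSamples:
    def test_recovers_noise_free_blocks_with_ordered_labels(self):
        df, truth = block_matrix(jitter=0.01)
        assignment = cluster_samples(df)
        est = [assignment.labels[c] for c in df.columns]
        assert adjusted_rand_score(truth, est) == 1.0
        # block at PDUI 0.9 must be called A, 0.3 must be C
        assert assignment.labels["g0s0"] == "A"
        assert assignment.labels["g2s0"] == "C"
        assert assignment.mean_pdui["A"] >= assignment.mean_pdui["B"] >= assignment.mean_pdui["C"]

    def test_identical_samples_fall_back_deterministically(self):
        df = pd.DataFrame(0.5, index=[f"G{i}" for i in range(10)], columns=list("abcdef"))
        with pytest.warns(UserWarning, match="indistinguishable"):
            a1 = cluster_samples(df)
        with pytest.warns(UserWarning):
            a2 = cluster_samples(df)
        assert a1.labels.equals(a2.labels)
        assert a1.labels.nunique() == 3

    def test_sample_order_invariance(self):
        df, _ = block_matrix(jitter=0.02, seed=3)
        a1 = cluster_samples(df)
        shuffled = df[list(reversed(df.columns))]
        a2 = cluster_samples(shuffled)
        assert all(a1.labels[c] == a2.labels[c] for c in df.columns)

    def test_na_handling_and_errors(self):
        df, _ = block_matrix()
        df.iloc[0, 0] = np.nan  # < 20% NA: gene kept, pairwise-complete distance
        cluster_samples(df)
        with pytest.raises(ValueError):
            cluster_samples(df.iloc[:, :2])
        with pytest.raises(ValueError):
            cluster_samples(df * np.nan)
        with pytest.raises(ValueError):
            cluster_samples(df + 1.5)


def two_group_assignment(n_per_group=20):
    from apakit import SubgroupAssignment

    labels = {}
    for i in range(n_per_group):
        labels[f"a{i}"] = "A"
        labels[f"b{i}"] = "B"
        labels[f"c{i}"] = "C"
    return SubgroupAssignment(
        labels=pd.Series(labels), mean_pdui={"A": 0.8, "B": 0.5, "C": 0.3}
    )


class TestDifferentialExpression:
    def test_flat_gene_is_ns_and_fourfold_gene_is_called(self, rng):
        groups = two_group_assignment()
        cols = list(groups.labels.index)
        base = rng.uniform(50, 150, 40)
        expr = pd.DataFrame(
            {c: base for c in cols}, index=[f"G{i}" for i in range(40)]
        )
        # gene G0: group C exactly 4x group A; G1: constant everywhere
        a_vals = rng.uniform(80, 120, 20)
        expr.loc["G0", [f"a{i}" for i in range(20)]] = a_vals
        expr.loc["G0", [f"c{i}" for i in range(20)]] = 4 * a_vals
        res = differential_expression(expr, groups)
        assert res.loc["G0", "log2_fold_change"] == pytest.approx(2.0, abs=0.05)
        assert res.loc["G0", "direction"] == "up_in_C"
        assert res.loc["G1", "direction"] == "ns"
        assert res.loc["G1", "p_value"] == 1.0

    def test_recovers_planted_degs_in_cohort(self, default_cohort):
        pdui, expr, truth = default_cohort
        groups = cluster_samples(pdui)
        res = differential_expression(expr, groups)
        for g in truth.deg_up_in_C:
            assert res.loc[g, "direction"] == "up_in_C"
        for g in truth.deg_down_in_C:
            assert res.loc[g, "direction"] == "down_in_C"

    def test_requires_group_sizes(self):
        groups = two_group_assignment()
        expr = pd.DataFrame(
            1.0, index=["G0"], columns=[c for c in groups.labels.index][:6]
        )
        with pytest.raises(ValueError):
            differential_expression(expr, groups)


def deg_frame(rows):
    return pd.DataFrame(
        rows, columns=["log2_fold_change", "p_value", "fdr", "direction"]
    ).set_index(pd.Index([f"G{i}" for i in range(len(rows))]))


class TestIntersectGenesets:
    def test_empty_degs_give_empty_output(self):
        degs = deg_frame([])
        assert intersect_genesets(degs, {"s": {"G0"}}) == []

    def test_union_membership_and_roles(self):
        degs = deg_frame(
            [(-2.0, 1e-4, 1e-3, "down_in_C")] * 5 + [(2.0, 1e-4, 1e-3, "up_in_C")]
        )
        sets = {"s1": {"G0", "G9"}, "s2": {"G3", "G5"}}
        out = intersect_genesets(degs, sets)
        assert {(c.gene_id, c.role) for c in out} == {
            ("G0", "lengthen_regulator"),
            ("G3", "lengthen_regulator"),
            ("G5", "shorten_regulator"),
        }
        assert all(c.in_geneset for c in out)

    def test_rejects_empty_genesets(self):
        with pytest.raises(ValueError):
            intersect_genesets(deg_frame([]), {})


class TestCorrelationScreen:
    def test_perfect_correlation(self):
        counts = pd.DataFrame(
            {"n_lengthened": [1, 4, 2, 8, 5], "n_shortened": [0, 0, 0, 0, 1]},
            index=list("abcde"),
        )
        expr = pd.DataFrame(
            [[1.0, 4.0, 2.0, 8.0, 5.0]], index=["G0"], columns=list("abcde")
        )
        cand = RegulatorCandidate("G0", role="lengthen_regulator", in_geneset=True)
        out = correlation_screen(expr, counts, [cand])
        assert len(out) == 1
        assert out[0].pearson_r == pytest.approx(1.0)

    def test_zero_variance_candidate_is_excluded_with_warning(self):
        counts = pd.DataFrame(
            {"n_lengthened": [1, 4, 2, 8], "n_shortened": [0, 1, 2, 3]},
            index=list("abcd"),
        )
        expr = pd.DataFrame([[3.0] * 4], index=["G0"], columns=list("abcd"))
        cand = RegulatorCandidate("G0", role="lengthen_regulator")
        with pytest.warns(UserWarning, match="zero-variance"):
            out = correlation_screen(expr, counts, [cand])
        assert out == []

    def test_planted_regulator_survives_screen(self, default_cohort):
        from apakit import apa_event_counts

        pdui, expr, truth = default_cohort
        counts = apa_event_counts(pdui)
        cands = [
            RegulatorCandidate(g, role="lengthen_regulator", in_geneset=True)
            for g in sorted(truth.lengthening_regulators)
        ]
        out = correlation_screen(expr, counts, cands)
        assert truth.key_regulator in {c.gene_id for c in out}


class TestOverlapCoreFactors:
    def test_empty_intersection(self):
        cand = RegulatorCandidate("G0", "lengthen_regulator", pearson_r=0.5)
        assert overlap_core_factors([cand], ["X1"]) == []

    def test_ranking_and_lexicographic_ties(self):
        cands = [
            RegulatorCandidate("B", "lengthen_regulator", pearson_r=0.5),
            RegulatorCandidate("A", "shorten_regulator", pearson_r=-0.5),
            RegulatorCandidate("C", "lengthen_regulator", pearson_r=0.9),
        ]
        out = overlap_core_factors(cands, ["A", "B", "C"])
        assert [c.gene_id for c in out] == ["C", "A", "B"]
        assert all(c.is_core_factor for c in out)
        with pytest.raises(ValueError):
            overlap_core_factors(cands, [])
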