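"""Unit and property tests for the two-isoform PDUI estimator."""

import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.stats import hypergeom

from apakit import (
    CoverageProfile,
    CoverageTruth,
    PDUIRecord,
    apa_event_counts,
    delta_pdui,
    estimate_pdui,
    simulate_coverage,
)
from apakit import test_apa_change as apa_change_test
from apakit.reference import brute_force_pdui

import pandas as pd


def make_profile(depth, gene="g"):
    return CoverageProfile(gene_id=gene, depth=np.asarray(depth, dtype=float))


def step_profile(length, site, high, low):
    return make_profile(np.r_[np.full(site, high), np.full(length - site, low)])


class TestEstimatePDUI:
    def test_single_isoform_limit_is_all_long(self):
        rec = estimate_pdui(make_profile(np.full(200, 100.0)))
        assert rec.status == "ok"
        assert rec.pdui == pytest.approx(1.0)
        assert rec.short_abundance == pytest.approx(0.0)

    def test_short_only_limit(self):
        rec = estimate_pdui(step_profile(200, 100, 100.0, 0.0))
        assert rec.pdui == pytest.approx(0.0)
        assert rec.proximal_site == 100

    def test_mixture_recovers_abundances(self):
        # long isoform 40 reads/base over the whole UTR, short 60 up to 100
        rec = estimate_pdui(step_profile(200, 100, 100.0, 40.0))
        assert rec.proximal_site == 100
        assert rec.long_abundance == pytest.approx(40.0)
        assert rec.short_abundance == pytest.approx(60.0)
        assert rec.pdui == pytest.approx(0.4)
        assert rec.fit_sse == pytest.approx(0.0, abs=1e-9)

    def test_low_coverage_paths(self):
        rec = estimate_pdui(make_profile(np.zeros(200)), min_mean_depth=0.0)
        assert rec.status == "low_coverage" and rec.pdui is None
        rec = estimate_pdui(make_profile(np.full(200, 2.0)), min_mean_depth=5.0)
        assert rec.status == "low_coverage"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_profile([])
        with pytest.raises(ValueError):
            make_profile([-1.0] * 10)
        with pytest.raises(ValueError):
            estimate_pdui(make_profile(np.ones(50)), end_margin=25)
        with pytest.raises(ValueError):
            estimate_pdui(make_profile(np.ones(50)), end_margin=0)

    def test_noise_free_round_trip_is_exact(self, rng):
        for _ in range(25):
            length = int(rng.integers(120, 400))
            site = int(rng.integers(50, length - 50))
            truth = CoverageTruth.from_pdui(
                "g", length, site, total_depth=float(rng.uniform(20, 100)),
                pdui_true=float(rng.uniform(0.05, 0.95)),
            )
            rec = estimate_pdui(simulate_coverage(truth), end_margin=50)
            assert rec.proximal_site == truth.proximal_site_true
            assert rec.pdui == pytest.approx(truth.pdui_true, abs=1e-9)

    def test_matches_brute_force_oracle_on_noisy_profiles(self, rng):
        margin = 20
        for i in range(60):
            length = int(rng.integers(2 * margin + 10, 301))
            truth = CoverageTruth.from_pdui(
                f"g{i}", length,
                int(rng.integers(margin, length - margin)),
                total_depth=float(rng.uniform(20, 120)),
                pdui_true=float(rng.uniform(0, 1)),
                noise_model="poisson",
                seed=int(rng.integers(0, 2**31)),
            )
            profile = simulate_coverage(truth)
            rec = estimate_pdui(profile, min_mean_depth=0.0, end_margin=margin)
            if rec.status != "ok":
                continue
            ref = brute_force_pdui(profile.depth, margin)
            assert rec.proximal_site == ref.proximal_site
            assert rec.fit_sse == pytest.approx(ref.sse, rel=1e-9, abs=1e-6)
            assert rec.pdui == pytest.approx(ref.pdui, abs=1e-9)

    def test_brute_force_closed_form_equals_scipy_nnls(self, rng):
        """The per-breakpoint closed form in the reference oracle is the
        true non-negative least-squares solution."""
        for _ in range(5):
            d = rng.poisson(60.0, size=150).astype(float)
            for site in rng.integers(10, 140, size=8):
                site = int(site)
                a = np.column_stack(
                    [(np.arange(150) < site).astype(float), np.ones(150)]
                )
                w, _ = nnls(a, d)
                m1, m2 = d[:site].mean(), d[site:].mean()
                if m1 >= m2:
                    w_s, w_l = m1 - m2, m2
                else:
                    w_s, w_l = 0.0, d.mean()
                assert w[0] == pytest.approx(w_s, abs=1e-8)
                assert w[1] == pytest.approx(w_l, abs=1e-8)

    def test_monotone_in_long_fraction(self):
        """On noise-free profiles a larger planted long fraction never
        lowers the estimated PDUI."""
        estimates = []
        for pdui_true in np.linspace(0.0, 1.0, 21):
            truth = CoverageTruth.from_pdui("g", 300, 150, 80.0, float(pdui_true))
            rec = estimate_pdui(simulate_coverage(truth))
            estimates.append(rec.pdui)
        assert all(b >= a - 1e-12 for a, b in zip(estimates, estimates[1:]))


def records(gene, pduis, w=50.0, length=200):
    out = []
    for i, p in enumerate(pduis):
        out.append(
            PDUIRecord(
                gene_id=gene, sample_id=f"s{i}",
                long_abundance=w * p, short_abundance=w * (1 - p),
                proximal_site=100, pdui=p, fit_sse=0.0, status="ok",
                utr_length=length,
            )
        )
    return out


class TestDeltaPDUI:
    def test_arithmetic(self):
        res = delta_pdui(records("g", [0.8, 0.8]), records("g", [0.6, 0.6]))
        assert res.delta_pdui == pytest.approx(0.2)
        assert res.call == "lengthened"

    def test_equal_groups_unchanged(self):
        res = delta_pdui(records("g", [0.5]), records("g", [0.5]))
        assert res.delta_pdui == 0.0 and res.call == "unchanged"

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = records("g", rng.uniform(0, 1, 4).tolist())
            b = records("g", rng.uniform(0, 1, 4).tolist())
            ab, ba = delta_pdui(a, b), delta_pdui(b, a)
            assert ab.delta_pdui == pytest.approx(-ba.delta_pdui)
            flip = {"lengthened": "shortened", "shortened": "lengthened",
                    "unchanged": "unchanged"}
            assert ba.call == flip[ab.call]

    def test_errors(self):
        with pytest.raises(ValueError):
            delta_pdui([], records("g", [0.5]))
        with pytest.raises(ValueError):
            delta_pdui(records("g", [0.5]), records("h", [0.5]))
        low = [PDUIRecord(gene_id="g", status="low_coverage")]
        with pytest.raises(ValueError):
            delta_pdui(low, records("g", [0.5]))


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n, k1, k2 = a + b + c + d, a + b, a + c
    dist = hypergeom(n, k1, k2)
    p_obs = dist.pmf(a)
    support = np.arange(max(0, k1 + k2 - n), min(k1, k2) + 1)
    return float(dist.pmf(support)[dist.pmf(support) <= p_obs * (1 + 1e-9)].sum())


class TestAPAChange:
    def test_strong_lengthening_matches_hypergeometric_oracle(self):
        # case pools to (900 long, 100 short), control to (100, 900)
        case = records("g", [0.9], w=5.0, length=200)
        ctrl = records("g", [0.1], w=5.0, length=200)
        res = apa_change_test(case, ctrl)
        assert res.call == "lengthened"
        assert res.p_value < 1e-6
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(900, 100, 100, 900), rel=1e-6
        )

    def test_identical_counts_give_p_one(self):
        res = apa_change_test(records("g", [0.5]), records("g", [0.5]))
        assert res.p_value == pytest.approx(1.0)
        assert res.call == "unchanged"

    def test_min_abs_delta_gates_the_call(self):
        # massive counts make p tiny, but |dPDUI| = 0.01 < 0.05
        case = records("g", [0.51], w=5000.0)
        ctrl = records("g", [0.50], w=5000.0)
        res = apa_change_test(case, ctrl, min_abs_delta=0.05)
        assert res.p_value < 0.05
        assert res.call == "unchanged"

    def test_zero_counts_unchanged(self):
        case = records("g", [0.5], w=0.0)
        case[0].long_abundance = case[0].short_abundance = 0.0
        res = apa_change_test(case, records("g", [0.9]))
        assert res.p_value == 1.0 and res.call == "unchanged"


class TestAPAEventCounts:
    def test_identical_samples_yield_zero(self):
        m = pd.DataFrame(0.5, index=[f"g{i}" for i in range(10)], columns=list("abc"))
        counts = apa_event_counts(m)
        assert (counts == 0).all().all()

    def test_constructed_lengthening(self):
        m = pd.DataFrame(0.5, index=[f"g{i}" for i in range(10)], columns=list("abcd"))
        m.loc[["g0", "g1", "g2", "g3", "g4", "g5", "g6"], "d"] = 0.8
        counts = apa_event_counts(m, event_threshold=0.2)
        assert counts.loc["d", "n_lengthened"] == 7
        assert counts.loc["a", "n_lengthened"] == 0

    def test_paired_normal_reference(self):
        m = pd.DataFrame(
            {"t1": [0.9, 0.2], "n1": [0.5, 0.5], "x": [0.5, 0.5]},
            index=["g0", "g1"],
        )
        counts = apa_event_counts(
            m, reference="paired_normal", normal_of={"t1": "n1"}
        )
        assert counts.loc["t1", "n_lengthened"] == 1
        assert counts.loc["t1", "n_shortened"] == 1
        with pytest.raises(ValueError):
            apa_event_counts(m, reference="paired_normal")

    def test_noise_free_cohort_counts_match_truth(self):
        from apakit import CohortEffects, simulate_cohort

        pdui, _, truth = simulate_cohort(
            effects=CohortEffects(pdui_noise_sd=0.0), seed=20240901
        )
        counts = apa_event_counts(pdui, event_threshold=0.2)
        planted = truth.event_counts().loc[counts.index]
        assert counts.equals(planted)
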