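"""MR estimators against closed forms, independent oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from sleepmet import ValidationError, egger, ivw, run_all_methods, wald_ratio, weighted_median
from sleepmet.mr import weighted_median_point
from conftest import make_harmonized
from oracles import weighted_median_oracle, wls_intercept_oracle, wls_origin_oracle


def _hset(bx, by, sy, sx=None):
    from sleepmet import HarmonizedSet

    n = len(bx)
    return HarmonizedSet(
        exposure_name="insomnia",
        outcome_name="met_001",
        table=pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "effect_allele": ["A"] * n,
                "other_allele": ["G"] * n,
                "beta_exp": bx,
                "se_exp": sx if sx is not None else [0.01] * n,
                "beta_out": by,
                "se_out": sy,
                "eaf_exp": [0.3] * n,
                "eaf_out": [0.3] * n,
            }
        ),
    )


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio({"beta_exp": 0.5, "beta_out": 0.1, "se_out": 0.05})
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        assert wald_ratio({"beta_exp": 0.5, "beta_out": 0.0, "se_out": 0.05}).theta == 0.0

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(ValidationError):
            wald_ratio({"beta_exp": 0.0, "beta_out": 0.1, "se_out": 0.05})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_delta_method_oracle(self, seed):
        r = np.random.default_rng(seed)
        bx, by, sy = r.normal(0.2, 0.05), r.normal(0, 0.1), r.uniform(0.01, 0.1)
        est = wald_ratio({"beta_exp": bx, "beta_out": by, "se_out": sy})
        assert est.theta == pytest.approx(by / bx, rel=1e-12)
        assert est.se == pytest.approx(sy / abs(bx), rel=1e-12)


class TestIvw:
    def test_collinear_ratios_give_exact_slope_and_zero_q(self):
        est = ivw(_hset([0.1, 0.2], [0.05, 0.10], [0.02, 0.03]))
        assert est.theta == pytest.approx(0.5, rel=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_four_snp_example_matches_wls_oracle(self):
        bx = [0.10, 0.20, 0.15, 0.12]
        by = [0.05, 0.09, 0.08, 0.05]
        sy = [0.02, 0.02, 0.02, 0.02]
        est = ivw(_hset(bx, by, sy, sx=[0.01] * 4))
        slope, se_fixed, q = wls_origin_oracle(bx, by, sy)
        assert est.theta == pytest.approx(slope, rel=1e-12)
        assert est.q_stat == pytest.approx(q, rel=1e-12)
        phi = max(1.0, np.sqrt(q / 3))
        assert est.se == pytest.approx(se_fixed * phi, rel=1e-12)

    def test_se_never_deflated_below_fixed(self, rng):
        h = make_harmonized(rng, 8)
        est = ivw(h)
        w = 1.0 / h.table["se_out"] ** 2
        se_fixed = float(np.sum(w * h.table["beta_exp"] ** 2)) ** -0.5
        assert est.se >= se_fixed - 1e-15

    def test_single_snp_redirects_to_wald(self, rng):
        with pytest.raises(ValidationError, match="wald"):
            ivw(make_harmonized(rng, 1))


class TestEgger:
    def test_noiseless_line_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.1 + 0.3 * bx
        est = egger(_hset(bx, by, [0.02] * 4))
        assert est.egger_intercept == pytest.approx(0.1, rel=1e-10)
        assert est.theta == pytest.approx(0.3, rel=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_wls_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = 8
        bx = np.abs(r.normal(0.1, 0.05, n)) + 0.01
        by = r.normal(0, 0.05, n)
        sy = r.uniform(0.01, 0.05, n)
        est = egger(_hset(bx, by, sy))
        intercept, slope, q, se0_u, se1_u = wls_intercept_oracle(bx, by, sy)
        phi = max(1.0, np.sqrt(q / (n - 2)))
        assert est.theta == pytest.approx(slope, rel=1e-10)
        assert est.egger_intercept == pytest.approx(intercept, rel=1e-10)
        assert est.se == pytest.approx(se1_u * phi, rel=1e-10)
        assert est.egger_intercept_se == pytest.approx(se0_u * phi, rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_statsmodels_wls(self, seed):
        r = np.random.default_rng(seed)
        n = 10
        bx = np.abs(r.normal(0.1, 0.05, n)) + 0.01
        by = r.normal(0, 0.05, n)
        sy = r.uniform(0.01, 0.05, n)
        est = egger(_hset(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert est.theta == pytest.approx(fit.params[1], rel=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)

    def test_internal_reorientation_makes_sign_irrelevant(self, rng):
        h = make_harmonized(rng, 9)
        flipped = h.table.copy()
        flip = flipped.index % 2 == 0
        flipped.loc[flip, "beta_exp"] *= -1
        flipped.loc[flip, "beta_out"] *= -1
        h2 = _hset(flipped["beta_exp"], flipped["beta_out"], flipped["se_out"])
        e1, e2 = egger(h), egger(h2)
        assert e1.theta == pytest.approx(e2.theta, rel=1e-12)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept, rel=1e-12)

    def test_constant_beta_exp_unidentifiable(self):
        with pytest.raises(ValidationError, match="unidentifiable"):
            egger(_hset([0.1, 0.1, 0.1], [0.02, 0.03, 0.01], [0.02] * 3))

    def test_too_few_snps(self, rng):
        with pytest.raises(ValidationError):
            egger(make_harmonized(rng, 2))


class TestWeightedMedian:
    def test_constant_ratios_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(_hset(bx, 0.4 * bx, [0.02, 0.05, 0.01]), seed=1)
        assert est.theta == pytest.approx(0.4, rel=1e-12)

    def test_symmetric_midpoint_of_three_equal_weights(self):
        # equal weights require bx^2/sy^2 constant
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.03])  # ratios 0.1, 0.2, 0.3
        est = weighted_median(_hset(bx, by, [0.02] * 3), seed=1)
        assert est.theta == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_point_estimate_matches_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 12))
        bx = r.normal(0.15, 0.05, n)
        bx[bx == 0] = 0.01
        by = r.normal(0.0, 0.05, n)
        sy = r.uniform(0.01, 0.05, n)
        est = weighted_median(_hset(bx, by, sy), seed=0, n_boot=10)
        expected = weighted_median_oracle(list(by / bx), list(bx**2 / sy**2))
        assert est.theta == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_bootstrap_se_reproducible_by_seed(self, rng):
        h = make_harmonized(rng, 6)
        a = weighted_median(h, seed=42, n_boot=200)
        b = weighted_median(h, seed=42, n_boot=200)
        c = weighted_median(h, seed=43, n_boot=200)
        assert a.se == b.se
        assert a.se != c.se

    def test_interpolation_core_handles_unsorted_input(self):
        assert weighted_median_point(
            np.array([0.3, 0.1, 0.2]), np.array([1.0, 1.0, 1.0])
        ) == pytest.approx(0.2)


class TestRunAllMethods:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (1, {"wald_ratio"}),
            (2, {"ivw_mre", "weighted_median"}),
            (10, {"ivw_mre", "egger", "weighted_median"}),
        ],
    )
    def test_method_gating_by_snp_count(self, rng, n, expected):
        ests = run_all_methods(make_harmonized(rng, n), seed=0, n_boot=50)
        assert {e.method for e in ests} == expected
        primary = [e for e in ests if e.primary]
        assert len(primary) == 1


class TestEstimatorProperties:
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 50))
    def test_scale_equivariance(self, c, seed):
        """Multiplying outcome betas and SEs by c scales theta and se by c."""
        r = np.random.default_rng(seed)
        n = 6
        bx = r.normal(0.15, 0.05, n)
        bx[bx == 0] = 0.01
        by, sy = r.normal(0, 0.05, n), r.uniform(0.01, 0.05, n)
        base, scaled = _hset(bx, by, sy), _hset(bx, c * by, c * sy)
        for fn in (ivw, egger):
            e0, e1 = fn(base), fn(scaled)
            assert e1.theta == pytest.approx(c * e0.theta, rel=1e-9, abs=1e-12)
            assert e1.se == pytest.approx(c * e0.se, rel=1e-9)
        w0 = weighted_median(base, seed=7, n_boot=50)
        w1 = weighted_median(scaled, seed=7, n_boot=50)
        assert w1.theta == pytest.approx(c * w0.theta, rel=1e-9, abs=1e-12)

    @given(seed=st.integers(0, 50))
    def test_instrument_orientation_invariance(self, seed):
        """Negating both betas of any SNP leaves every estimator unchanged."""
        r = np.random.default_rng(seed)
        n = 7
        bx = r.normal(0.15, 0.05, n)
        bx[bx == 0] = 0.01
        by, sy = r.normal(0, 0.05, n), r.uniform(0.01, 0.05, n)
        sign = r.choice([-1.0, 1.0], n)
        base, flipped = _hset(bx, by, sy), _hset(sign * bx, sign * by, sy)
        assert ivw(base).theta == pytest.approx(ivw(flipped).theta, rel=1e-12)
        assert egger(base).theta == pytest.approx(egger(flipped).theta, rel=1e-12)
        wm0 = weighted_median(base, seed=3, n_boot=10)
        wm1 = weighted_median(flipped, seed=3, n_boot=10)
        assert wm0.theta == pytest.approx(wm1.theta, rel=1e-12)

    def test_two_identical_wald_ratios_q_zero(self):
        est = ivw(_hset([0.1, 0.3], [0.04, 0.12], [0.01, 0.02]))
        assert est.theta == pytest.approx(0.4, rel=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-18)
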