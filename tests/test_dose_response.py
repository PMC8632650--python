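"""Linear-quadratic calibration: ML fit, dispersion diagnostics, exact CIs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.special import xlogy

from cytodose.dose_response import (
    DosePoint,
    DoseResponseCurve,
    curve_from_json,
    curve_to_json,
    curves_summary_frame,
    dispersion_stats,
    exact_poisson_ci,
    fit_lq,
    points_from_tallies,
    yield_at,
    yield_se_at,
)
from cytodose.synthetic_cohort import make_cohort_spec, reference_curve, simulate_tallies


def brute_force_ml(points, starts=((0.01, 0.1, 0.05), (0.001, 0.2, 0.08), (0.05, 0.05, 0.02))):
    """Independent Poisson log-likelihood maximizer (multi-start simplex)."""
    d = np.array([p.dose_gy for p in points], float)
    n = np.array([p.n_cells for p in points], float)
    y = np.array([p.n_aberrations for p in points], float)
    x = np.column_stack([np.ones_like(d), d, d * d])

    def nll(theta):
        mu = n * (x @ np.abs(theta))
        if np.any(mu[y > 0] <= 0):
            return np.inf
        return float(np.sum(mu) - np.sum(xlogy(y, mu)))

    best = None
    for s in starts:
        r = optimize.minimize(
            nll, s, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 20000, "maxfev": 20000},
        )
        if best is None or r.fun < best.fun:
            best = r
    return np.abs(best.x)


def make_curve(C=0.0, alpha=0.1, beta=0.05, vcov=None):
    vcov = np.zeros((3, 3)) if vcov is None else np.asarray(vcov, float)
    ses = np.sqrt(np.clip(np.diag(vcov), 0, None))
    return DoseResponseCurve(
        endpoint="dicentrics", C=C, alpha=alpha, beta=beta,
        se_C=ses[0], se_alpha=ses[1], se_beta=ses[2],
        vcov=vcov, dispersion_scale=1.0, n_points=5,
    )


class TestFitLq:
    def test_matches_brute_force_maximizer_on_toy_data(self):
        points = [DosePoint(0.0, 500, 2), DosePoint(1.0, 400, 80),
                  DosePoint(2.0, 300, 180), DosePoint(4.0, 200, 350)]
        curve = fit_lq(points)
        oracle = brute_force_ml(points)
        for got, want in zip((curve.C, curve.alpha, curve.beta), oracle):
            assert got == pytest.approx(want, rel=1e-4, abs=1e-7)

    def test_matches_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            C, a, b = rng.uniform(0, 0.01), rng.uniform(0.02, 0.3), rng.uniform(0.01, 0.15)
            doses = sorted(rng.choice([0, 0.25, 0.5, 1, 1.5, 2, 3, 4], 5, replace=False))
            pts = []
            for d in doses:
                n = int(rng.integers(200, 2000))
                pts.append(DosePoint(float(d), n, int(rng.poisson(n * (C + a * d + b * d * d)))))
            curve = fit_lq(pts)
            oracle = brute_force_ml(pts)
            for got, want in zip((curve.C, curve.alpha, curve.beta), oracle):
                assert got == pytest.approx(want, rel=1e-4, abs=1e-6)

    def test_agrees_with_glm_on_interior_solution(self):
        """Cross-check against an identity-link Poisson GLM with cells as exposure."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        C, a, b = 0.02, 0.15, 0.06
        pts = [DosePoint(d, 5000, int(rng.poisson(5000 * (C + a * d + b * d * d))))
               for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        curve = fit_lq(pts)
        d = np.array([p.dose_gy for p in pts])
        n = np.array([p.n_cells for p in pts], float)
        y = np.array([p.n_aberrations for p in pts], float)
        exog = n[:, None] * np.column_stack([np.ones_like(d), d, d * d])
        glm = sm.GLM(y, exog, family=sm.families.Poisson(sm.families.links.Identity()))
        res = glm.fit(start_params=[C, a, b])
        assert curve.C == pytest.approx(res.params[0], rel=1e-4)
        assert curve.alpha == pytest.approx(res.params[1], rel=1e-4)
        assert curve.beta == pytest.approx(res.params[2], rel=1e-4)

    def test_recovers_senegal_preset_within_3se(self):
        spec = make_cohort_spec("senegal_africa", cells_per_dose=5000, seed=1,
                                dispersion=1.0)
        curve = fit_lq(points_from_tallies(simulate_tallies(spec), "dicentrics"))
        assert abs(curve.alpha - 0.168) < 3 * curve.se_alpha
        assert abs(curve.beta - 0.061) < 3 * curve.se_beta

    def test_all_zero_counts_give_flagged_degenerate_fit(self):
        pts = [DosePoint(d, 100, 0) for d in (0, 1, 2)]
        curve = fit_lq(pts)
        assert curve.degenerate
        assert (curve.C, curve.alpha, curve.beta) == (0.0, 0.0, 0.0)

    def test_needs_three_distinct_doses(self):
        with pytest.raises(ValueError, match="distinct doses"):
            fit_lq([DosePoint(0, 10, 0), DosePoint(0, 10, 1), DosePoint(1, 10, 2)])

    def test_dispersion_scale_floored_at_one(self):
        rng = np.random.default_rng(8)
        pts = [DosePoint(d, 1000, int(rng.poisson(1000 * 0.1 * (1 + d))))
               for d in (0, 0.5, 1, 2, 4)]
        assert fit_lq(pts).dispersion_scale >= 1.0

    def test_overdispersed_counts_inflate_standard_errors(self):
        rng = np.random.default_rng(12)
        spec_p = make_cohort_spec("senegal_africa", cells_per_dose=3000, seed=21,
                                  dispersion=1.0)
        spec_od = make_cohort_spec("senegal_africa", cells_per_dose=3000, seed=21,
                                   dispersion=4.0)
        c_p = fit_lq(points_from_tallies(simulate_tallies(spec_p), "dicentrics"))
        c_od = fit_lq(points_from_tallies(simulate_tallies(spec_od), "dicentrics"))
        assert c_od.dispersion_scale > c_p.dispersion_scale

    def test_vcov_diagonal_equals_squared_ses(self, senegal_calibration_curve):
        c = senegal_calibration_curve
        assert np.allclose(np.diag(c.vcov), [c.se_C**2, c.se_alpha**2, c.se_beta**2])


class TestYieldEvaluation:
    def test_senegal_yield_at_4gy(self):
        c = make_curve(C=0.0, alpha=0.168, beta=0.061)
        assert yield_at(c, 4.0) == pytest.approx(1.648)

    def test_caucasian_yield_at_1gy(self):
        c = make_curve(C=0.0, alpha=0.147, beta=0.128)
        assert yield_at(c, 1.0) == pytest.approx(0.275)

    def test_yield_at_zero_is_background(self):
        assert yield_at(make_curve(C=0.013), 0.0) == pytest.approx(0.013)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            yield_at(make_curve(), -1.0)

    @given(st.floats(0, 10), st.floats(0, 10))
    def test_monotone_when_coefficients_non_negative(self, d1, d2):
        c = make_curve(C=0.001, alpha=0.1, beta=0.05)
        lo, hi = sorted([d1, d2])
        assert yield_at(c, lo) <= yield_at(c, hi)

    def test_se_with_identity_vcov(self):
        c = make_curve(vcov=np.eye(3))
        assert yield_se_at(c, 2.0) == pytest.approx(math.sqrt(21), rel=1e-12)

    def test_se_with_zero_vcov_is_zero(self):
        assert yield_se_at(make_curve(), 3.0) == 0.0

    def test_se_with_diagonal_vcov(self):
        c = make_curve(vcov=np.diag([0.2, 0.3, 0.4]))
        assert yield_se_at(c, 1.0) == pytest.approx(math.sqrt(0.9))

    def test_non_psd_vcov_rejected(self):
        v = np.array([[1, 0, 0], [0, 1e-4, 0.1], [0, 0.1, 1e-4]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            yield_se_at(make_curve(vcov=v), 1.0)


class TestDispersionStats:
    def test_hand_computed_bimodal_example(self):
        s = dispersion_stats([0] * 50 + [2] * 50)
        assert s.mean_y == 1.0
        assert s.variance == pytest.approx(100 / 99)
        assert s.dispersion_index == pytest.approx(1.0101, abs=1e-4)
        assert s.u_value == pytest.approx((100 / 99 - 1) * math.sqrt(99 / 1.98), rel=1e-12)
        assert s.u_value == pytest.approx(0.07142, abs=1e-5)

    def test_constant_counts_underdispersed(self):
        small = dispersion_stats([3, 3, 3, 3])
        assert small.variance == 0.0 and small.dispersion_index == 0.0
        assert small.u_value < 0
        # with enough cells the degenerate distribution is flagged decisively
        assert dispersion_stats([3] * 100).u_value < -1.96

    def test_u_undefined_for_fewer_than_two_events(self):
        assert dispersion_stats([0, 0, 0, 1]).u_value is None
        assert dispersion_stats([0, 0]).u_value is None

    def test_poisson_counts_look_poisson(self):
        rng = np.random.default_rng(4)
        s = dispersion_stats(rng.poisson(1.6, 10_000))
        assert 0.95 < s.dispersion_index < 1.05
        assert not s.poisson_rejected

    def test_needs_at_least_two_cells(self):
        with pytest.raises(ValueError):
            dispersion_stats([1])


class TestExactPoissonCi:
    def garwood_oracle(self, x, conf):
        """Invert the Poisson cdf directly (independent of chi-square quantiles)."""
        a = (1 - conf) / 2
        lower = 0.0 if x == 0 else optimize.brentq(
            lambda lam: stats.poisson.sf(x - 1, lam) - a, 1e-12, 100)
        upper = optimize.brentq(lambda lam: stats.poisson.cdf(x, lam) - a, 1e-12, 100)
        return lower, upper

    @pytest.mark.parametrize("x,expected", [
        (0, (0.0, 3.6889)),
        (10, (4.7954, 18.3904)),
    ])
    def test_known_bounds(self, x, expected):
        lo, hi = exact_poisson_ci(x, 0.95)
        assert lo == pytest.approx(expected[0], abs=1e-3)
        assert hi == pytest.approx(expected[1], abs=1e-3)

    @pytest.mark.parametrize("x", [0, 1, 5, 10, 40])
    def test_matches_cdf_inversion_oracle(self, x):
        lo, hi = exact_poisson_ci(x, 0.95)
        olo, ohi = self.garwood_oracle(x, 0.95)
        assert lo == pytest.approx(olo, abs=1e-8)
        assert hi == pytest.approx(ohi, abs=1e-8)

    def test_interval_brackets_the_count_and_widens_with_conf(self):
        for x in (0, 3, 17):
            lo95, hi95 = exact_poisson_ci(x, 0.95)
            lo99, hi99 = exact_poisson_ci(x, 0.99)
            assert lo95 <= x <= hi95
            assert lo99 <= lo95 and hi99 >= hi95

    def test_simulated_coverage_at_least_nominal(self):
        rng = np.random.default_rng(14)
        for lam in (0.5, 2.0, 10.0):
            draws = rng.poisson(lam, 2000)
            hits = sum(1 for x in draws
                       if (ci := exact_poisson_ci(int(x), 0.95))[0] <= lam <= ci[1])
            assert hits / 2000 >= 0.95

    def test_conf_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            exact_poisson_ci(3, 1.0)


class TestSerialization:
    def test_curve_json_round_trip(self, senegal_calibration_curve):
        payload = curve_to_json(senegal_calibration_curve)
        back = curve_from_json(payload)
        assert back.alpha == senegal_calibration_curve.alpha
        assert np.allclose(back.vcov, senegal_calibration_curve.vcov)
        assert len(payload["vcov"]) == 9

    def test_summary_reports_published_ratio(self):
        frame = curves_summary_frame([reference_curve("senegal_africa", "dicentrics")],
                                     ["senegal_africa"])
        assert frame.loc[0, "alpha_beta_ratio"] == pytest.approx(2.75)
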