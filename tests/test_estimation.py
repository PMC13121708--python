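"""Titer, completion, alpha-curve and kinetic fits: oracles and recovery."""

import math

import numpy as np
import pytest

import dropphage as dp
from dropphage.core import PL_TO_ML, p_lysis, expected_lambdas
from dropphage.estimation import (
    AlphaLysisModel,
    DlaMeasurement,
    LysisKineticsModel,
    digital_titer,
    dla_titer,
    fit_alpha_curve,
    fit_kinetics,
    lysis_completion_analysis,
    titer_timecourse,
)
from statsmodels.stats.proportion import proportion_confint


class TestDigitalTiter:
    def test_zero_fraction_gives_zero_titer(self):
        t = digital_titer(0.0, (0.0, 0.001), 0.5, 50.0, 20.0)
        assert t.c_p == 0.0 and t.ci_low == 0.0

    def test_monotone_in_positive_fraction(self):
        titers = [digital_titer(p, (p, p), 0.5, 50.0, 20.0).c_p
                  for p in (0.1, 0.3, 0.5, 0.8)]
        assert all(b > a for a, b in zip(titers, titers[1:]))

    def test_simulator_recovery_with_ci_coverage(self):
        true_c_p = 1e8
        spec = dp.EmulsionSpec(
            n_droplets=100_000, alpha_mode="fixed", alpha_values=0.5,
            volume_modes=((50.0, 1.0),), c_p=true_c_p, c_b_nominal=1.6e9, seed=6)
        ev, _truth = dp.simulate_emulsion(spec)
        fit = dp.fit_mixture(ev.green_peak, seed=0)
        p, ci = dp.positive_fraction(fit)
        lam_b = 0.5 * 1.6e9 * 50 * PL_TO_ML
        est = digital_titer(p, ci, 0.5, 50.0, lam_b)
        assert est.c_p == pytest.approx(true_c_p, rel=0.05)
        assert est.ci_low <= true_c_p <= est.ci_high

    def test_ci_coverage_rate(self):
        """Wilson CI propagated through the inversion covers ~95% of truths."""
        rng = np.random.default_rng(33)
        true_c_p, alpha, v, lam_b, n = 1e8, 0.5, 50.0, 40.0, 40_000
        p_true = p_lysis(alpha * true_c_p * v * PL_TO_ML, lam_b)
        covered = 0
        reps = 80
        for _ in range(reps):
            k = rng.binomial(n, p_true)
            lo, hi = proportion_confint(k, n, method="wilson")
            est = digital_titer(k / n, (float(lo), float(hi)), alpha, v, lam_b)
            covered += est.ci_low <= true_c_p <= est.ci_high
        assert covered / reps >= 0.90

    def test_infeasible_upper_bound_flagged(self):
        lam_b = -math.log(0.2)  # ceiling 0.8
        est = digital_titer(0.75, (0.7, 0.85), 0.5, 50.0, lam_b)
        assert est.infeasible_upper and est.ci_high == math.inf


class TestLysisCompletion:
    def test_perfect_agreement_gives_unit_fractions(self):
        dla, c_b, v = 1e8, 1e9, 50.0
        groups = []
        for a in (0.2, 0.4, 0.6, 0.8):
            groups.append((a, p_lysis(*expected_lambdas(a, dla, c_b, v)), 1000))
        lc = lysis_completion_analysis(groups, dla, c_b, v)
        assert np.allclose(lc.table.f, 1.0, atol=1e-12)
        assert lc.slope == pytest.approx(0.0, abs=1e-12)

    def test_ratio_arithmetic(self):
        lc = lysis_completion_analysis(
            [(0.3, 0.3, 100), (0.6, 0.2, 100)], 1e8, 1e9, 50.0)
        a, p_exp = 0.3, 0.3
        p_th = p_lysis(*expected_lambdas(a, 1e8, 1e9, 50.0))
        assert lc.table.f.iloc[0] == pytest.approx(p_exp / p_th, rel=1e-12)

    def test_reduced_effective_density_lowers_f(self):
        """Simulated at 30% effective density: f < 1, stable across seeds.

        Densities are chosen so the effective occupancy is O(1); at large
        lambda_b the bacterial factor saturates and f returns to 1.
        """
        dla, c_b_nom, v = 2e7, 2e8, 50.0
        outcomes = []
        for seed in (8, 9):
            groups = []
            for a in (0.3, 0.5, 0.7):
                spec = dp.EmulsionSpec(
                    n_droplets=20_000, alpha_mode="fixed", alpha_values=a,
                    volume_modes=((v, 1.0),), c_p=dla, c_b_nominal=c_b_nom,
                    c_b_effective=0.3 * c_b_nom, seed=seed)
                _ev, truth = dp.simulate_emulsion(spec)
                groups.append((a, truth.is_positive.mean(), 20_000))
            lc = lysis_completion_analysis(groups, dla, c_b_nom, v)
            outcomes.append(lc.table.f.to_numpy())
            assert (lc.table.f < 1.0).all()
        assert np.abs(outcomes[0] - outcomes[1]).max() < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            lysis_completion_analysis([(0.5, 0.5, 10)], 1e8, 1e9, 50.0)


class TestAlphaCurveFit:
    def _noiseless_bins(self, c_p, c_b, v, alphas=None):
        alphas = alphas if alphas is not None else np.linspace(0.05, 0.95, 30)
        return [(a, p_lysis(*expected_lambdas(a, c_p, c_b, v)), 2000)
                for a in alphas]

    def test_noiseless_exact_recovery(self):
        c_p, c_b, v = 1.2e8, 5e8, 15.0
        fit = fit_alpha_curve(self._noiseless_bins(c_p, c_b, v), v)
        assert fit.c_p == pytest.approx(c_p, rel=1e-6)
        assert fit.c_b_effective == pytest.approx(c_b, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_effective_fraction_and_od_reporting(self):
        c_p, c_b, v = 1.2e8, 5e8, 15.0
        fit = fit_alpha_curve(self._noiseless_bins(c_p, c_b, v), v,
                              rho_cells_per_od=8e8, c_b_nominal=2e9)
        assert fit.effective_fraction == pytest.approx(0.25, rel=1e-6)
        assert fit.od_effective == pytest.approx(c_b / 8e8, rel=1e-6)

    def test_estimator_interface_and_determinism(self):
        bins = self._noiseless_bins(1.2e8, 5e8, 15.0)
        a = [b[0] for b in bins]
        p = [b[1] for b in bins]
        n = [b[2] for b in bins]
        m1 = AlphaLysisModel(volume_pl=15.0).fit(a, p, sample_weight=n)
        m2 = AlphaLysisModel(volume_pl=15.0).fit(a, p, sample_weight=n)
        assert m1.c_p_ == m2.c_p_ and m1.c_b_effective_ == m2.c_b_effective_
        pred = m1.predict([0.5])
        assert pred[0] == pytest.approx(
            p_lysis(*expected_lambdas(0.5, 1.2e8, 5e8, 15.0)), rel=1e-6)

    def test_narrow_alpha_range_rejected(self):
        bins = self._noiseless_bins(1e8, 5e8, 15.0,
                                    alphas=np.linspace(0.45, 0.55, 12))
        with pytest.raises(ValueError, match="range"):
            fit_alpha_curve(bins, 15.0)

    def test_degenerate_bins_rejected(self):
        bins = [(a, 0.0, 100) for a in np.linspace(0.1, 0.9, 12)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_alpha_curve(bins, 15.0)


def _kinetic_points(c_p, tau, k_cb, alpha, v, times, n=10_000):
    a = alpha * c_p * v * PL_TO_ML
    r = (1 - alpha) * k_cb
    pts = []
    for t in times:
        at = -math.expm1(-r * max(t - tau, 0.0))
        pts.append((t, -math.expm1(-a * at), n))
    return pts


class TestKineticFit:
    times8 = (10, 30, 60, 100, 150, 220, 350, 600)

    def test_noiseless_exact_recovery(self):
        c_p, tau, k_cb = 8.3e7, 24.6, 0.0061
        pts = _kinetic_points(c_p, tau, k_cb, 0.5, 40.0, self.times8)
        fit = fit_kinetics(pts, 0.5, 40.0)
        assert fit.c_p == pytest.approx(c_p, rel=1e-6)
        assert fit.tau_min == pytest.approx(tau, abs=1e-4)
        assert fit.k_cb_per_min == pytest.approx(k_cb, rel=1e-6)

    def test_plateau_matches_occupancy_limit(self):
        pts = _kinetic_points(8.3e7, 24.6, 0.0061, 0.5, 40.0, self.times8)
        fit = fit_kinetics(pts, 0.5, 40.0)
        assert fit.plateau == pytest.approx(
            -math.expm1(-0.5 * fit.c_p * 40 * PL_TO_ML), rel=1e-12)

    def test_zero_lag_recovered_as_small(self):
        pts = _kinetic_points(8.3e7, 0.0, 0.0061, 0.5, 40.0, self.times8)
        fit = fit_kinetics(pts, 0.5, 40.0)
        assert fit.tau_min < 2.0

    def test_all_plateau_unidentifiable(self):
        pts = _kinetic_points(8.3e7, 5.0, 10.0, 0.5, 40.0, (100, 200, 300, 400))
        with pytest.raises(ValueError, match="plateau"):
            fit_kinetics(pts, 0.5, 40.0)

    def test_too_few_points_rejected(self):
        pts = _kinetic_points(8.3e7, 24.6, 0.0061, 0.5, 40.0, (30, 60, 100))
        with pytest.raises(ValueError, match="4 time points"):
            fit_kinetics(pts, 0.5, 40.0)

    def test_low_occupancy_warns(self):
        pts = _kinetic_points(8.3e7, 24.6, 0.0061, 0.5, 40.0, self.times8)
        with pytest.warns(UserWarning, match="lambda_b"):
            fit_kinetics(pts, 0.5, 40.0, lambda_b=3.0)

    def test_estimator_determinism(self):
        pts = _kinetic_points(8.3e7, 24.6, 0.0061, 0.5, 40.0, self.times8)
        t = [q[0] for q in pts]
        p = [q[1] for q in pts]
        m1 = LysisKineticsModel(alpha=0.5, volume_pl=40.0).fit(t, p)
        m2 = LysisKineticsModel(alpha=0.5, volume_pl=40.0).fit(t, p)
        assert (m1.c_p_, m1.tau_min_, m1.k_cb_per_min_) == \
               (m2.c_p_, m2.tau_min_, m2.k_cb_per_min_)

    def test_adsorption_constant_derivation(self):
        pts = _kinetic_points(8.3e7, 24.6, 0.0061, 0.5, 40.0, self.times8)
        fit = fit_kinetics(pts, 0.5, 40.0).with_adsorption_constant(1.83e9, 0.286)
        assert fit.k_ml_per_min == pytest.approx(
            0.0061 / (0.286 * 1.83e9), rel=1e-6)

    def test_shared_kinetics_across_size_modes(self):
        """Two droplet sizes with one generative process give matching rates."""
        c_p, tau, k_cb, alpha = 8.3e7, 24.6, 0.0061, 0.5
        times = [20.0, 60.0, 120.0, 200.0, 350.0, 600.0]
        fits = {}
        for v in (40.0, 80.0):
            spec = dp.EmulsionSpec(
                n_droplets=60_000, alpha_mode="fixed", alpha_values=alpha,
                volume_modes=((v, 1.0),), c_p=c_p, c_b_nominal=1.83e9,
                c_b_effective=0.286 * 1.83e9,
                kinetics=dp.KineticTruth(k_cb_per_min=k_cb, tau_min=tau), seed=12)
            course = dp.simulate_timecourse(spec, times_min=times)
            fracs = dp.timecourse_positive_fractions(
                [ev.green_peak for ev, _ in course], seed=2)
            pts = [(t, p, n) for t, (p, _, n) in zip(times, fracs)]
            fits[v] = fit_kinetics(pts, alpha, v,
                                   lambda_b=(1 - alpha) * 0.286 * 1.83e9 * v * PL_TO_ML)
        ratio = fits[40.0].k_cb_per_min / fits[80.0].k_cb_per_min
        assert 0.8 < ratio < 1.25
        for v in (40.0, 80.0):
            assert fits[v].c_p == pytest.approx(c_p, rel=0.10)


class TestTiterTimecourse:
    def test_noiseless_curve_converges_to_titer(self):
        c_p, tau, k_cb, alpha, v = 8.3e7, 24.6, 0.0061, 0.5, 40.0
        times = (10, 50, 150, 400, 2000)
        pts = _kinetic_points(c_p, tau, k_cb, alpha, v, times, n=10**6)
        out = titer_timecourse(pts, alpha, v, lambda_b=1e3)
        a_t = [-math.expm1(-(1 - alpha) * k_cb * max(t - tau, 0)) for t in times]
        for est, at in zip(out, a_t):
            assert est.c_p == pytest.approx(c_p * at, rel=1e-3)
        assert out[0].c_p == 0.0  # pre-lag point
        assert out[-1].c_p == pytest.approx(c_p, rel=0.01)

    def test_simulator_final_time_recovery(self):
        c_p = 8.3e7
        spec = dp.EmulsionSpec(
            n_droplets=50_000, alpha_mode="fixed", alpha_values=0.5,
            volume_modes=((40.0, 1.0),), c_p=c_p, c_b_nominal=1.83e9,
            c_b_effective=0.286 * 1.83e9,
            kinetics=dp.KineticTruth(k_cb_per_min=0.0061, tau_min=24.6), seed=13)
        (ev, _truth), = dp.simulate_timecourse(spec, times_min=[2000.0])
        fit = dp.fit_mixture(ev.green_peak, seed=0)
        p, ci = dp.positive_fraction(fit)
        lam_b = 0.5 * 0.286 * 1.83e9 * 40 * PL_TO_ML
        (est,) = titer_timecourse([(2000.0, p, len(ev))], 0.5, 40.0, lam_b)
        assert est.c_p == pytest.approx(c_p, rel=0.10)


class TestDla:
    @pytest.mark.parametrize("counts,expected", [
        ((25, 25), 2.5e7),
        ((24, 26), 2.5e7),
        ((0,), 0.0),
    ])
    def test_titer_arithmetic(self, counts, expected):
        meas = DlaMeasurement(plaque_counts=counts, dilution_factor=1e5,
                              plated_volume_ml=0.1)
        assert dla_titer(meas) == pytest.approx(expected, rel=1e-12)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            DlaMeasurement(plaque_counts=(10,), dilution_factor=1e3,
                           plated_volume_ml=0.0)
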