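"""GMM digitization: mode recovery, P_L accuracy, silhouette, controls."""

import numpy as np
import pytest

import dropphage as dp
from dropphage.digitize import (
    AmbiguousDigitizationError,
    DropletDigitizer,
    classify_with_control,
    fit_mixture,
    negative_reference,
    positive_fraction,
    silhouette_score,
    timecourse_positive_fractions,
)


def _lognormal_modes(rng, n, weights, means, sd=0.15):
    """Draw from a mixture of log-normal modes (natural-log parameters)."""
    comp = rng.choice(len(weights), size=n, p=weights)
    return np.exp(rng.normal(np.asarray(means)[comp], sd)), comp


class TestFitMixture:
    def test_two_mode_weight_recovery(self):
        rng = np.random.default_rng(5)
        x, _ = _lognormal_modes(rng, 50_000, [0.7, 0.3], [5.0, 7.0])
        fit = fit_mixture(x, seed=0)
        assert fit.n_components == 2
        assert fit.weights[0] == pytest.approx(0.7, abs=0.02)
        assert fit.P_L == pytest.approx(0.3, abs=0.02)

    def test_single_mode_selects_k1(self):
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(5.0, 0.15, 20_000))
        fit = fit_mixture(x, seed=0)
        assert fit.n_components == 1
        assert fit.P_L == 0.0

    def test_three_tier_summed_upper_modes(self):
        rng = np.random.default_rng(7)
        x, _ = _lognormal_modes(rng, 50_000, [0.5, 0.3, 0.2], [5.0, 6.2, 7.4])
        fit = fit_mixture(x, seed=0)
        assert fit.n_components == 3
        assert fit.P_L == pytest.approx(0.5, abs=0.02)

    def test_requires_enough_droplets(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture(np.ones(30) * 10.0)

    def test_rejects_nonpositive_signals(self):
        x = np.concatenate([np.full(100, 10.0), [-1.0]])
        with pytest.raises(ValueError, match="positive"):
            fit_mixture(x)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        x, _ = _lognormal_modes(rng, 10_000, [0.6, 0.4], [5.0, 7.0])
        f1 = fit_mixture(x, seed=3)
        f2 = fit_mixture(x, seed=3)
        assert np.array_equal(f1.weights, f2.weights)
        assert np.array_equal(f1.hard_labels, f2.hard_labels)

    def test_gain_invariance_of_positive_fraction(self):
        """A detector gain change shifts all log-means equally; P_L is unmoved."""
        rng = np.random.default_rng(9)
        x, _ = _lognormal_modes(rng, 20_000, [0.6, 0.4], [5.0, 7.0])
        p1 = fit_mixture(x, seed=0).P_L
        p2 = fit_mixture(x * 37.5, seed=0).P_L
        assert p2 == pytest.approx(p1, abs=1e-3)

    def test_model_selection_bounded_by_tiers(self):
        """Chosen K never exceeds generative tiers + 1 (checked over seeds)."""
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            x, _ = _lognormal_modes(rng, 20_000, [0.5, 0.35, 0.15],
                                    [5.0, 6.0, 7.0])
            fit = fit_mixture(x, seed=seed)
            assert fit.n_components <= 4

    def test_estimator_predict_matches_labels(self):
        rng = np.random.default_rng(10)
        x, _ = _lognormal_modes(rng, 5_000, [0.6, 0.4], [5.0, 7.0])
        dig = DropletDigitizer(random_state=0).fit(x)
        assert np.array_equal(dig.predict(x), dig.labels_)

    def test_sklearn_param_interface(self):
        dig = DropletDigitizer(k_max=3)
        assert dig.get_params()["k_max"] == 3
        dig.set_params(k_max=2)
        assert dig.k_max == 2


class TestPositiveFraction:
    def test_methods_agree_when_separated(self):
        rng = np.random.default_rng(11)
        x, _ = _lognormal_modes(rng, 50_000, [0.7, 0.3], [5.0, 7.0])
        fit = fit_mixture(x, seed=0)
        vals = [positive_fraction(fit, method=m)[0]
                for m in ("weights", "hard", "posterior")]
        assert max(vals) - min(vals) < 0.01
        assert vals[0] == pytest.approx(0.30, abs=0.02)

    def test_wilson_interval_brackets_estimate(self):
        rng = np.random.default_rng(12)
        x, _ = _lognormal_modes(rng, 10_000, [0.5, 0.5], [5.0, 7.0])
        p, (lo, hi) = positive_fraction(fit_mixture(x, seed=0))
        assert lo < p < hi
        assert hi - lo < 0.03

    def test_single_mode_requires_control(self):
        rng = np.random.default_rng(13)
        x = np.exp(rng.normal(5.0, 0.15, 5_000))
        fit = fit_mixture(x, seed=0)
        with pytest.raises(AmbiguousDigitizationError):
            positive_fraction(fit)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(14)
        x, _ = _lognormal_modes(rng, 1_000, [0.5, 0.5], [5.0, 7.0])
        with pytest.raises(ValueError, match="method"):
            positive_fraction(fit_mixture(x, seed=0), method="magic")


class TestControlClassification:
    def _control_fit(self, rng, mean=5.0):
        return fit_mixture(np.exp(rng.normal(mean, 0.15, 5_000)), seed=0)

    def test_sample_identical_to_control_is_negative(self):
        rng = np.random.default_rng(15)
        control = self._control_fit(rng)
        sample = self._control_fit(rng)
        out = classify_with_control(sample, control)
        assert positive_fraction(out)[0] == 0.0

    def test_shifted_sample_is_positive(self):
        rng = np.random.default_rng(16)
        control = self._control_fit(rng)
        sample = self._control_fit(rng, mean=5.0 + 6 * 0.15)
        out = classify_with_control(sample, control)
        assert positive_fraction(out)[0] == 1.0

    def test_spontaneous_tail_false_positive_rate(self):
        """Bacteria-only emulsion: positives stay below the spontaneous rate."""
        p_spont = 0.002
        fluor = dp.FluorescenceModel(spontaneous_lysis_prob=p_spont)
        spec = dp.EmulsionSpec(
            n_droplets=50_000, alpha_mode="fixed", alpha_values=0.5,
            volume_modes=((50.0, 1.0),), c_p=0.0, c_b_nominal=1.6e9, seed=21)
        ev, truth = dp.simulate_emulsion(spec, fluor)
        control = dp.simulate_emulsion(
            spec, dp.FluorescenceModel(spontaneous_lysis_prob=0.0))[0]
        sample_fit = fit_mixture(ev.green_peak, seed=0)
        control_fit = fit_mixture(control.green_peak, seed=0)
        out = classify_with_control(sample_fit, control_fit)
        p, _ = positive_fraction(out)
        lam_b = 0.5 * 1.6e9 * 50e-9
        expected = -np.expm1(-lam_b * p_spont)
        se = np.sqrt(expected * (1 - expected) / len(ev))
        assert p <= expected + 2 * se

    def test_timecourse_polarization(self):
        """Early all-negative aliquots are polarized by a late multimodal one."""
        rng = np.random.default_rng(17)
        early = np.exp(rng.normal(5.0, 0.15, 5_000))
        late, _ = _lognormal_modes(rng, 5_000, [0.4, 0.6], [5.0, 7.0])
        fracs = timecourse_positive_fractions([early, late], seed=0)
        assert fracs[0][0] == 0.0
        assert fracs[1][0] == pytest.approx(0.6, abs=0.03)

    def test_all_single_mode_without_control_raises(self):
        rng = np.random.default_rng(18)
        a = np.exp(rng.normal(5.0, 0.15, 2_000))
        with pytest.raises(AmbiguousDigitizationError):
            timecourse_positive_fractions([a, a], seed=0)

    def test_negative_reference_extraction(self):
        rng = np.random.default_rng(19)
        late, _ = _lognormal_modes(rng, 5_000, [0.4, 0.6], [5.0, 7.0])
        ref = negative_reference(fit_mixture(late, seed=0))
        assert ref.n_components == 1
        assert ref.means[0] == pytest.approx(5.0, abs=0.05)


class TestSilhouette:
    def test_perfect_separation_scores_one(self):
        x = np.concatenate([np.full(500, 0.0), np.full(500, 100.0)])
        x += np.tile([0.0, 1e-6], 500)  # break exact ties
        labels = np.concatenate([np.zeros(500), np.ones(500)])
        assert silhouette_score(x, labels) >= 0.99

    def test_random_labels_score_near_zero(self):
        rng = np.random.default_rng(20)
        x = rng.normal(0.0, 1.0, 10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(silhouette_score(x, labels, seed=0)) < 0.05

    def test_two_mode_simulated_range(self):
        """4-sigma-separated modes land in the published mid-0.6 regime."""
        scores = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(30 + seed)
            x, _ = _lognormal_modes(rng, 20_000, [0.5, 0.5], [5.0, 5.6], sd=0.15)
            fit = fit_mixture(x, seed=seed)
            scores.append(silhouette_score(np.log(x), fit.hard_labels, seed=seed))
        assert all(0.5 < s < 0.8 for s in scores)
        assert max(scores) - min(scores) < 0.04

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            silhouette_score(np.arange(200.0), np.zeros(200))

    def test_small_subsample_cap_rejected(self):
        with pytest.raises(ValueError, match="subsample_cap"):
            silhouette_score(np.arange(200.0),
                             np.r_[np.zeros(100), np.ones(100)], subsample_cap=10)


class TestSimulatorFidelity:
    @pytest.mark.parametrize("alpha,lambda_p", [(0.1, 0.05), (0.5, 0.5), (0.9, 2.0)])
    def test_p_l_tracks_truth(self, alpha, lambda_p):
        v = 50.0
        c_p = lambda_p / (alpha * v * 1e-9)
        c_b = 40.0 / ((1 - alpha) * v * 1e-9)  # lambda_b = 40
        spec = dp.EmulsionSpec(
            n_droplets=20_000, alpha_mode="fixed", alpha_values=alpha,
            volume_modes=((v, 1.0),), c_p=c_p, c_b_nominal=c_b, seed=41)
        ev, truth = dp.simulate_emulsion(spec)
        fit = fit_mixture(ev.green_peak, seed=1)
        p, _ = positive_fraction(fit)
        assert p == pytest.approx(truth.is_positive.mean(), abs=0.01)
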