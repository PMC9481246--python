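"""Repeat-level generative models and their statistics."""

import numpy as np
import pytest
from scipy import stats

from driftlab import models, theory

UNIFORM_SD = np.sqrt(1.0 / 12.0)


def _mean_rs(resp):
    rho = models.repeat_rs_matrix(resp)
    iu, ju = np.triu_indices(resp.n_repeats, k=1)
    return float(rho[iu, ju].mean())


class TestGainModel:
    def test_seed_determinism(self):
        p = models.GainModelParams(n_units=50, n_repeats=10, seed=3)
        a = models.simulate_gain_model(p)
        b = models.simulate_gain_model(p)
        np.testing.assert_array_equal(a.responses, b.responses)
        np.testing.assert_array_equal(a.behavior, b.behavior)

    def test_signal_frozen_noise_redrawn(self):
        r = models.simulate_gain_model(
            models.GainModelParams(n_units=100, n_repeats=5, seed=0)
        )
        assert r.signal.shape == (100,)
        # responses differ across repeats (noise redrawn)
        assert not np.allclose(r.responses[0], r.responses[1])

    def test_unscaled_mean_rs_is_half(self):
        # sigma_S = sigma_N -> rho = 1/2; g pinned to 1
        p = models.GainModelParams(
            n_units=2000, n_repeats=40, gain_range=(1.0, 1.0 + 1e-12),
            variant="both", seed=1,
        )
        assert _mean_rs(models.simulate_gain_model(p)) == pytest.approx(
            0.5, abs=0.02
        )

    def test_signal_variant_large_equal_gains_rs_near_one(self):
        p = models.GainModelParams(
            n_units=1000, n_repeats=10, gain_range=(100.0, 100.0 + 1e-9),
            variant="signal", seed=2,
        )
        assert _mean_rs(models.simulate_gain_model(p)) > 0.99

    def test_both_variant_rs_distribution_gain_invariant(self):
        # scaling S and N together cancels: RS distribution should not
        # depend on the gain range (KS test at alpha=0.01)
        def sample(gain_range, seed):
            p = models.GainModelParams(
                n_units=500, n_repeats=21, gain_range=gain_range,
                variant="both", seed=seed,
            )
            rho = models.repeat_rs_matrix(models.simulate_gain_model(p))
            iu, ju = np.triu_indices(21, k=1)
            return rho[iu, ju]

        a = sample((0.5, 2.0), 5)
        b = sample((1.0, 7.0), 6)
        assert stats.ks_2samp(a, b).pvalue > 0.01

    @pytest.mark.parametrize("variant,theory_fn", [
        ("both", theory.rs_both_scaled),
        ("signal", theory.rs_signal_scaled),
        ("noise", theory.rs_noise_scaled),
    ])
    def test_monte_carlo_matches_theory(self, variant, theory_fn):
        p = models.GainModelParams(
            n_units=1000, n_repeats=30, variant=variant, seed=7
        )
        r = models.simulate_gain_model(p)
        rho = models.repeat_rs_matrix(r)
        iu, ju = np.triu_indices(30, k=1)
        expected = np.mean([
            theory_fn(UNIFORM_SD, UNIFORM_SD, r.behavior[i], r.behavior[j])
            for i, j in zip(iu, ju)
        ])
        assert float(rho[iu, ju].mean()) == pytest.approx(expected, abs=0.02)


class TestExtendedGain:
    def test_seed_determinism(self):
        p = models.ExtendedGainParams(n_units=50, n_repeats=10, seed=1)
        a = models.simulate_extended_gain(p)
        b = models.simulate_extended_gain(p)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_untuned_unit_is_pure_noise(self):
        p = models.ExtendedGainParams(n_units=200, n_repeats=100, seed=2)
        r = models.simulate_extended_gain(p)
        k = int(np.argmin(r.tuning))  # weakest-tuned unit
        rel = models.unit_reliability(r)
        assert abs(rel[k]) < 0.15
        # strongly tuned units are reliable
        assert rel[int(np.argmax(r.tuning))] > 0.5

    def test_reliability_tracks_behavior_modulation(self):
        r = models.simulate_extended_gain(models.ExtendedGainParams(seed=3))
        reg = models.reliability_modulation_regression(r)
        assert reg["slope"] > 0
        assert reg["r2"] > 0.4


class TestIndependentModel:
    def test_seed_determinism(self):
        p = models.IndependentModelParams(n_units=50, n_repeats=10, seed=4)
        a = models.simulate_independent(p)
        b = models.simulate_independent(p)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_zero_behavior_tuning_reduces_to_unscaled_gain(self):
        p = models.IndependentModelParams(
            n_units=2000, n_repeats=30, tuning_range=(0.0, 0.0), seed=5
        )
        r = models.simulate_independent(p)
        assert _mean_rs(r) == pytest.approx(
            theory.rs_unscaled(UNIFORM_SD, UNIFORM_SD), abs=0.02
        )

    def test_equal_beta_matches_independent_closed_form(self):
        # behavioural pattern redrawn per repeat: beta acts as pure
        # noise, matching the marginal closed form
        p = models.IndependentModelParams(
            n_units=2000, n_repeats=30, beta_range=(1.5, 1.5 + 1e-12),
            refresh_tuning=True, seed=6,
        )
        expected = theory.rs_independent(
            UNIFORM_SD, UNIFORM_SD, UNIFORM_SD, 1.5, 1.5
        )
        assert _mean_rs(models.simulate_independent(p)) == pytest.approx(
            expected, abs=0.02
        )

    def test_frozen_tuning_matches_covariance_form(self):
        p = models.IndependentModelParams(n_units=2000, n_repeats=30, seed=7)
        r = models.simulate_independent(p)
        rho = models.repeat_rs_matrix(r)
        iu, ju = np.triu_indices(30, k=1)
        expected = np.mean([
            theory.rs_independent_frozen_tuning(
                UNIFORM_SD, UNIFORM_SD, UNIFORM_SD,
                r.behavior[i], r.behavior[j],
            )
            for i, j in zip(iu, ju)
        ])
        assert float(rho[iu, ju].mean()) == pytest.approx(expected, abs=0.02)

    def test_no_reliability_modulation_relation(self):
        p = models.IndependentModelParams(
            n_units=1000, n_repeats=200, n_stimuli=10, seed=8
        )
        reg = models.reliability_modulation_regression(
            models.simulate_independent(p)
        )
        assert reg["r2"] < 0.05


class TestRSVsRelativeBehavior:
    def test_bin_means_equal_brute_force(self):
        r = models.simulate_gain_model(
            models.GainModelParams(n_units=100, n_repeats=15, seed=9)
        )
        curve = models.rs_vs_relative_behavior(r, n_bins=10)
        edges = curve["bin_edges"]
        ratios, sims = curve["relative_behavior"], curve["rs"]
        for k in range(10):
            mask = (
                (ratios >= edges[k]) & (ratios < edges[k + 1])
                if k < 9
                else (ratios >= edges[k]) & (ratios <= edges[k + 1])
            )
            if mask.any():
                assert curve["bin_means"][k] == pytest.approx(
                    sims[mask].mean()
                )

    def test_signal_gain_curve_peaks_at_unity(self):
        r = models.simulate_gain_model(
            models.GainModelParams(variant="signal", n_repeats=60, seed=10)
        )
        curve = models.rs_vs_relative_behavior(r)
        centers, means = curve["bin_centers"], curve["bin_means"]
        peak = centers[np.nanargmax(means)]
        assert abs(peak - 1.0) < 0.3
        # falls away on both sides of 1
        assert np.nanmax(means) > means[0]
        assert np.nanmax(means) > means[-1]

    def test_constant_gain_gives_unit_abscissa(self):
        r = models.simulate_gain_model(
            models.GainModelParams(
                n_units=50, n_repeats=8, gain_range=(1.0, 1.0 + 1e-12), seed=11
            )
        )
        curve = models.rs_vs_relative_behavior(r)
        np.testing.assert_allclose(curve["relative_behavior"], 1.0)

    def test_symmetric_cloud_both_orderings(self):
        r = models.simulate_gain_model(
            models.GainModelParams(n_units=50, n_repeats=8, seed=12)
        )
        curve = models.rs_vs_relative_behavior(r)
        n_pairs = 8 * 7 // 2
        assert len(curve["relative_behavior"]) == 2 * n_pairs
        ratios = np.sort(curve["relative_behavior"])
        np.testing.assert_allclose(
            np.sort(1.0 / ratios), ratios, rtol=1e-10
        )
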