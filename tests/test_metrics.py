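"""Drift statistics: RS, RDI, reliability, tuning, SCI, regressions."""

import numpy as np
import pandas as pd
import pytest

from driftlab import metrics as m
from driftlab import slice_repeats
from driftlab.session import DegenerateInputError, RepeatTensor


def _tensor(data, blocks=None):
    data = np.asarray(data, dtype=float)
    r = data.shape[0]
    return RepeatTensor(
        data=data,
        blocks=np.zeros(r, dtype=int) if blocks is None else np.asarray(blocks),
        unit_ids=np.arange(data.shape[1]),
        stimulus_name="movie",
    )


class TestPopulationVectors:
    def test_concatenation_order_unit_major(self):
        t = _tensor([[[1, 2, 3], [4, 5, 6]]])
        np.testing.assert_allclose(
            m.population_vectors(t)[0], [1, 2, 3, 4, 5, 6]
        )

    def test_zscore_variant_has_zero_unit_means(self):
        rng = np.random.default_rng(0)
        t = _tensor(rng.poisson(5, (4, 3, 6)))
        v = m.population_vectors(t, use_zscore=True)
        per_unit = v.reshape(4, 3, 6)
        np.testing.assert_allclose(
            per_unit.transpose(1, 0, 2).reshape(3, -1).mean(axis=1),
            0.0, atol=1e-12,
        )


class TestRSMatrix:
    def test_hand_values(self):
        vecs = np.array([[1, 2, 3], [3, 2, 1], [1, 2, 3]], dtype=float)
        rs = m.rs_matrix(vecs)
        assert rs.rho[0, 1] == pytest.approx(-1.0)
        assert rs.rho[0, 2] == pytest.approx(1.0)

    def test_orthogonal_binary_vectors(self):
        rs = m.rs_matrix(
            np.array([[1, 0, 1, 0], [1, 1, 0, 0]], dtype=float)
        )
        assert rs.rho[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(1)
        vecs = rng.normal(size=(5, 50))
        rs = m.rs_matrix(vecs)
        for i in range(5):
            for j in range(5):
                expected = np.corrcoef(vecs[i], vecs[j])[0, 1]
                assert rs.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_marked_missing(self):
        vecs = np.array([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]],
                        dtype=float)
        rs = m.rs_matrix(vecs)
        assert np.isnan(rs.rho[0, 1]) and np.isnan(rs.rho[2, 0])
        assert rs.rho[1, 2] == pytest.approx(-1.0)

    def test_pairwise_complete_with_floor(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a.copy()
        b[:4] = np.nan  # only 2/6 shared -> below the 50% floor
        rs = m.rs_matrix(np.array([a, b]))
        assert np.isnan(rs.rho[0, 1])


class TestDriftSummary:
    def test_hand_value(self):
        # CCws=0.8, CCbs=0.4 -> RDI = 0.4/1.2 = 1/3
        rho = np.array([
            [1.0, 0.8, 0.4, 0.4],
            [0.8, 1.0, 0.4, 0.4],
            [0.4, 0.4, 1.0, 0.8],
            [0.4, 0.4, 0.8, 1.0],
        ])
        rs = m.RSMatrix(rho=rho, blocks=np.array([0, 0, 1, 1]))
        summary = m.drift_summary(rs)
        assert summary.cc_within == pytest.approx(0.8)
        assert summary.cc_between == pytest.approx(0.4)
        assert summary.rdi == pytest.approx(1.0 / 3.0)

    def test_equal_means_give_zero(self):
        rho = np.full((4, 4), 0.6)
        np.fill_diagonal(rho, 1.0)
        rs = m.RSMatrix(rho=rho, blocks=np.array([0, 0, 1, 1]))
        assert m.drift_summary(rs).rdi == pytest.approx(0.0)

    def test_invariant_to_relabelling_within_blocks(self):
        rng = np.random.default_rng(2)
        vecs = rng.normal(size=(6, 40))
        blocks = np.array([0, 0, 0, 1, 1, 1])
        base = m.drift_summary(m.rs_matrix(vecs, blocks))
        perm = np.array([2, 0, 1, 5, 3, 4])  # permute within blocks
        permuted = m.drift_summary(m.rs_matrix(vecs[perm], blocks[perm]))
        assert permuted.cc_within == pytest.approx(base.cc_within)
        assert permuted.cc_between == pytest.approx(base.cc_between)

    def test_requires_two_blocks(self):
        rs = m.rs_matrix(np.random.default_rng(0).normal(size=(4, 10)))
        with pytest.raises(ValueError):
            m.drift_summary(rs)


class TestPairwiseRdi:
    @pytest.mark.parametrize("rho,expected", [
        (1.0, 0.0), (0.0, 1.0), (0.5, 1.0 / 3.0),
    ])
    def test_values(self, rho, expected):
        assert m.pairwise_rdi(rho) == pytest.approx(expected)

    def test_perfect_anticorrelation_flagged_infinite(self):
        assert np.isinf(m.pairwise_rdi(-1.0))


class TestStimulusReliability:
    def test_identical_repeats_give_one(self):
        frame = np.array([1.0, 3, 2, 5])
        t = _tensor(np.broadcast_to(frame, (3, 2, 4)).copy())
        rel = m.stimulus_reliability(t)
        np.testing.assert_allclose(rel["reliability"], 1.0)

    def test_random_modulation_near_zero(self):
        rng = np.random.default_rng(3)
        t = _tensor(5.0 + rng.uniform(0, 1, size=(20, 100, 30)))
        rel = m.stimulus_reliability(t)
        assert abs(rel["reliability"].mean()) < 0.02

    def test_two_repeats_equals_single_pair_correlation(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(2, 3, 8))
        rel = m.stimulus_reliability(_tensor(data))
        for k in range(3):
            expected = np.corrcoef(data[0, k], data[1, k])[0, 1]
            assert rel["reliability"][k] == pytest.approx(expected)

    def test_single_unit_population_rs_equals_reliability(self):
        # RS of a one-unit population vector is that unit's reliability
        rng = np.random.default_rng(5)
        data = rng.normal(size=(4, 1, 10))
        rel = m.stimulus_reliability(_tensor(data))
        rs = m.rs_matrix(m.population_vectors(_tensor(data)))
        iu, ju = rs.off_diagonal_pairs()
        assert rel["reliability"][0] == pytest.approx(
            rs.rho[iu, ju].mean()
        )

    def test_constant_unit_missing(self):
        data = np.zeros((3, 2, 5))
        data[:, 1, :] = np.random.default_rng(0).normal(size=(3, 5))
        rel = m.stimulus_reliability(_tensor(data))
        assert np.isnan(rel["reliability"][0])
        assert rel["n_constant_repeats"][0] == 3


class TestSetpointSimilarity:
    def test_identical_setpoints_give_one(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(1, 10, size=5)
        data = np.zeros((3, 5, 4)) + base[None, :, None]
        data += rng.normal(0, 1e-9, size=data.shape)
        rs = m.setpoint_similarity(_tensor(data))
        iu, ju = rs.off_diagonal_pairs()
        np.testing.assert_allclose(rs.rho[iu, ju], 1.0, atol=1e-6)

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(0, 5, size=(3, 8, 4))
        shifted = data.copy()
        shifted[1] += 3.7  # common additive offset on one repeat
        a = m.setpoint_similarity(_tensor(data)).rho
        b = m.setpoint_similarity(_tensor(shifted)).rho
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_independent_setpoints_near_zero(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(10, 1000, 1))
        rs = m.setpoint_similarity(_tensor(data))
        iu, ju = rs.off_diagonal_pairs()
        assert abs(rs.rho[iu, ju].mean()) < 0.02

    def test_single_frame_variant(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(3, 6, 4))
        rs = m.setpoint_similarity(_tensor(data), frame=2)
        expected = np.corrcoef(data[:, :, 2])
        np.testing.assert_allclose(rs.rho, expected, atol=1e-12)


class TestBehaviorCorrelation:
    def test_proportional_series(self):
        x = np.linspace(0, 1, 50)
        assert m.behavior_correlation(3 * x, x) == pytest.approx(1.0)
        assert m.behavior_correlation(-3 * x, x) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=(2, 10_000))
        assert abs(m.behavior_correlation(a, b)) < 0.05

    def test_too_few_bins_error(self):
        with pytest.raises(ValueError):
            m.behavior_correlation(np.ones(5), np.ones(5))

    def test_constant_series_missing(self):
        assert np.isnan(
            m.behavior_correlation(np.ones(20), np.linspace(0, 1, 20))
        )


class TestBootstrapZ:
    def test_z_formula(self):
        # strong linear coupling: z = (rho - mu_sh) / sigma_sh exactly
        rng = np.random.default_rng(11)
        b = rng.normal(size=200)
        a = b + rng.normal(0, 0.5, size=200)
        out = m.bootstrap_z(a, b, n_shuffles=50, seed=0)
        assert out["z"] == pytest.approx(
            (out["rho"] - out["mu_shuffle"]) / out["sigma_shuffle"]
        )
        assert out["significant"]

    def test_seed_determinism(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=(2, 100))
        z1 = m.bootstrap_z(a, b, seed=42)
        z2 = m.bootstrap_z(a, b, seed=42)
        assert z1 == z2

    def test_requires_two_shuffles(self):
        with pytest.raises(ValueError):
            m.bootstrap_z(np.ones(20), np.ones(20), n_shuffles=1)


class TestSignConstancy:
    def test_identical_and_negated(self):
        r = np.array([0.5, -0.2, 0.9, -0.7])
        assert m.sign_constancy_index(r, r) == 1.0
        assert m.sign_constancy_index(r, -r) == 0.0

    def test_zero_counts_as_positive(self):
        assert m.sign_constancy_index(
            np.array([0.0, 0.0]), np.array([0.3, -0.3])
        ) == 0.5

    def test_independent_signs_near_half(self):
        rng = np.random.default_rng(13)
        r1, r2 = rng.normal(size=(2, 4000))
        assert m.sign_constancy_index(r1, r2) == pytest.approx(0.5, abs=0.03)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            m.sign_constancy_index(np.array([np.nan]), np.array([1.0]))


class TestRSVsPupilRegression:
    def _rs(self, rho, blocks):
        return m.RSMatrix(rho=rho, blocks=np.asarray(blocks))

    def test_exactly_linear_recovered(self):
        pupil = np.array([0.0, 1.0, 2.0, 4.0])
        rho = np.ones((4, 4))
        for i in range(4):
            for j in range(4):
                rho[i, j] = 1.0 - 0.1 * abs(pupil[i] - pupil[j])
        out = m.rs_vs_pupil_regression(
            self._rs(rho, [0, 0, 1, 1]), pupil
        )
        assert out["slope"] == pytest.approx(-0.1)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_shuffled_rs_near_zero_r2(self):
        rng = np.random.default_rng(14)
        n = 40
        pupil = rng.normal(size=n)
        rho = np.ones((n, n))
        iu, ju = np.triu_indices(n, k=1)
        vals = rng.normal(size=len(iu))
        rho[iu, ju] = vals
        rho[ju, iu] = vals
        out = m.rs_vs_pupil_regression(
            self._rs(rho, [0] * (n // 2) + [1] * (n // 2)), pupil
        )
        assert out["r2"] < 0.02

    def test_percentile_filter_keeps_top_fifth(self):
        rng = np.random.default_rng(15)
        n = 21
        pupil = rng.normal(size=n)
        running = rng.normal(size=n)
        rho = np.ones((n, n))
        out = m.rs_vs_pupil_regression(
            self._rs(rho, [0] * 10 + [1] * 11), pupil,
            running_means=running, running_percentile=80.0,
        )
        n_pairs = n * (n - 1) // 2
        assert out["pairs"]["kept"].sum() == int(np.ceil(0.2 * n_pairs))


class TestStimulusSetpointComparison:
    def test_seed_determinism(self):
        from driftlab.synth import SynthConfig, simulate_session

        cfg = SynthConfig(n_units=15, repeats_per_block=3,
                          second_stimulus="drifting_gratings", gap_bins=200)
        s, _ = simulate_session(cfg, 0)
        a = m.stimulus_setpoint_comparison(
            s, "natural_movie_1", "drifting_gratings", n_frames=20,
            n_pairs=10, seed=5,
        )
        b = m.stimulus_setpoint_comparison(
            s, "natural_movie_1", "drifting_gratings", n_frames=20,
            n_pairs=10, seed=5,
        )
        for stim in a["per_stimulus"]:
            assert a["per_stimulus"][stim] == b["per_stimulus"][stim]

    def test_stable_stimulus_has_higher_similarity(self):
        # the movie blocks straddle the behavioural step while the
        # grating blocks sit inside the gap under one state: cross-block
        # setpoint similarity should be lower for the movie
        from driftlab.synth import SynthConfig, simulate_session

        sims_movie, sims_grating = [], []
        for seed in range(3):
            cfg = SynthConfig(
                repeats_per_block=5, second_stimulus="drifting_gratings",
                gap_bins=400,
            )
            s, _ = simulate_session(cfg, 30 + seed)
            out = m.stimulus_setpoint_comparison(
                s, "natural_movie_1", "drifting_gratings", n_pairs=30,
                seed=seed,
            )
            sims_movie.append(out["per_stimulus"]["natural_movie_1"]["mean"])
            sims_grating.append(
                out["per_stimulus"]["drifting_gratings"]["mean"]
            )
        assert np.mean(sims_movie) < np.mean(sims_grating)

    def test_insufficient_frames_error(self, tiny_session):
        with pytest.raises(ValueError):
            m.stimulus_setpoint_comparison(
                tiny_session, "movie", "movie", n_frames=50
            )


class TestRepeatBehaviorMeans:
    def test_zscored_means(self, small_session):
        s, _ = small_session
        t = slice_repeats(s, "natural_movie_1")
        means = m.repeat_behavior_means(s, t, "pupil_width")
        assert means.shape == (t.n_repeats,)
        # block-2 repeats have higher arousal on average
        assert means[t.blocks == 1].mean() > means[t.blocks == 0].mean()
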