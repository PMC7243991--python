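"""Naive Bayes decoder: scoring variants, metrics, splits, and sweeps."""

import numpy as np
import pytest

import caldecode as cd
from caldecode.core import EXCLUDED, BinaryRaster
from caldecode.decoder import DecoderModel
from conftest import make_stateseq


def _model(likelihood, marginal, prior=None, variant="log_product",
           centers=None):
    likelihood = np.atleast_2d(np.asarray(likelihood, dtype=float))
    n, m = likelihood.shape
    prior = np.full(m, 1.0 / m) if prior is None else np.asarray(prior)
    centers = (np.arange(m, dtype=float)[:, None] if centers is None
               else np.asarray(centers))
    return DecoderModel(likelihood=likelihood,
                        marginal=np.atleast_1d(np.asarray(marginal, float)),
                        prior=prior, observed_prior=prior.copy(),
                        prior_mode="uniform", scoring_variant=variant,
                        state_ids=np.arange(m), centers=centers,
                        neuron_ids=np.arange(n), sampling_rate=30.0,
                        n_states_full=m)


class TestBuildDecoder:
    def test_worked_example_wraps_tuning(self):
        seq = make_stateseq([0] * 5 + [1] * 5, 2)
        raster = BinaryRaster(np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 1]]), 30.0)
        model = cd.build_decoder(raster, seq)
        np.testing.assert_allclose(model.likelihood, [[0.4, 0.2]])
        assert model.marginal[0] == pytest.approx(0.3)

    def test_uniform_prior(self, raster_rise_1d, stateseq_1d):
        model = cd.build_decoder(raster_rise_1d, stateseq_1d, "uniform")
        np.testing.assert_allclose(model.prior, 1.0 / model.n_states)

    def test_all_silent_rejected(self):
        seq = make_stateseq([0, 1] * 5, 2)
        with pytest.raises(ValueError):
            cd.build_decoder(BinaryRaster(np.zeros((3, 10)), 30.0), seq)

    def test_silent_neurons_dropped(self):
        seq = make_stateseq([0, 1] * 5, 2)
        states = np.zeros((2, 10), dtype=np.uint8)
        states[1, 0] = 1
        model = cd.build_decoder(BinaryRaster(states, 30.0), seq)
        np.testing.assert_array_equal(model.neuron_ids, [1])


class TestDecodePosteriors:
    def test_one_hot_likelihood(self):
        model = _model([[0.0, 1.0, 0.0]], [1 / 3])
        raster = BinaryRaster(np.array([[1]]), 30.0)
        traj = cd.decode_posteriors(raster, model)
        np.testing.assert_allclose(traj.posteriors[0], [0.0, 1.0, 0.0])
        assert traj.map_state[0] == 1

    def test_no_active_neuron_falls_back_to_prior(self):
        model = _model([[0.9, 0.1]], [0.5], prior=np.array([0.7, 0.3]))
        raster = BinaryRaster(np.array([[0]]), 30.0)
        traj = cd.decode_posteriors(raster, model)
        np.testing.assert_allclose(traj.posteriors[0], [0.7, 0.3])
        assert not traj.decodable[0]
        assert traj.map_state[0] == EXCLUDED

    def test_log_map_equals_linear_product_oracle(self):
        """200 random zero-free instances: log-domain MAP == brute force."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 9)
            m = rng.integers(2, 13)
            lik = rng.uniform(0.01, 1.0, (n, m))
            marg = rng.uniform(0.05, 0.9, n)
            prior = rng.dirichlet(np.ones(m))
            active = rng.random(n) < 0.6
            active[rng.integers(0, n)] = True      # ensure evidence
            model = _model(lik, marg, prior=prior)
            traj = cd.decode_posteriors(
                BinaryRaster(active[:, None].astype(np.uint8), 30.0), model)
            direct = np.prod((lik * prior[None, :]
                              / marg[:, None])[active], axis=0)
            assert traj.map_state[0] == int(np.argmax(direct))

    def test_window_sums_past_scores(self):
        """Windowed score equals brute-force sum over the trailing frames."""
        rng = np.random.default_rng(1)
        lik = rng.uniform(0.05, 1.0, (4, 6))
        model = _model(lik, rng.uniform(0.1, 0.5, 4))
        active = (rng.random((4, 50)) < 0.3).astype(np.uint8)
        raster = BinaryRaster(active, 30.0)
        window_s = 5 / 30.0                         # L = 5 frames
        traj = cd.decode_posteriors(raster, model, window_s)
        from caldecode.decoder import _log_scores
        per_frame = _log_scores(active.astype(bool), model)
        for t in (0, 3, 20, 49):
            lo = max(0, t - 4)
            manual = per_frame[lo:t + 1].sum(axis=0)
            if np.isfinite(manual).any() and active[:, lo:t + 1].sum() > 0:
                post = np.exp(manual - manual.max())
                post /= post.sum()
                np.testing.assert_allclose(traj.posteriors[t], post, atol=1e-12)

    def test_negative_window_rejected(self):
        model = _model([[0.5, 0.5]], [0.5])
        with pytest.raises(ValueError):
            cd.decode_posteriors(BinaryRaster(np.array([[1]]), 30.0), model, -1.0)

    def test_posterior_rows_sum_to_one(self, raster_rise_1d, stateseq_1d):
        model = cd.build_decoder(raster_rise_1d, stateseq_1d)
        traj = cd.decode_posteriors(raster_rise_1d, model, 0.5)
        sums = traj.posteriors[traj.decodable].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_unbiased_equals_uniform_under_log_product(self, raster_rise_1d,
                                                       stateseq_1d):
        """P(A_k)->1 is a state-independent constant: with normalized
        log-product scoring the MAP cannot change..."""
        m_u = cd.build_decoder(raster_rise_1d, stateseq_1d, "uniform", "log_product")
        m_n = cd.build_decoder(raster_rise_1d, stateseq_1d, "unbiased", "log_product")
        t_u = cd.decode_posteriors(raster_rise_1d, m_u)
        t_n = cd.decode_posteriors(raster_rise_1d, m_n)
        np.testing.assert_array_equal(t_u.map_state, t_n.map_state)

    def test_unbiased_differs_under_log1p(self, raster_rise_1d, stateseq_1d):
        """...but under log1p the constant enters nonlinearly and can."""
        m_u = cd.build_decoder(raster_rise_1d, stateseq_1d, "uniform", "log1p")
        m_n = cd.build_decoder(raster_rise_1d, stateseq_1d, "unbiased", "log1p")
        t_u = cd.decode_posteriors(raster_rise_1d, m_u)
        t_n = cd.decode_posteriors(raster_rise_1d, m_n)
        both = (t_u.map_state != EXCLUDED) & (t_n.map_state != EXCLUDED)
        assert np.any(t_u.map_state[both] != t_n.map_state[both])


class TestMapEstimate:
    def test_argmax_and_tie_break(self):
        post = np.array([[0.1, 0.7, 0.2], [0.5, 0.5, 0.0]])
        np.testing.assert_array_equal(cd.map_estimate(post), [1, 0])

    def test_all_nan_row_flagged(self):
        out = cd.map_estimate(np.array([[np.nan, np.nan], [0.4, 0.6]]))
        np.testing.assert_array_equal(out, [EXCLUDED, 1])


class TestMetrics:
    def test_agreement(self):
        assert cd.decoding_agreement(np.array([0, 1, 2, 3]),
                                     np.array([0, 1, 9, 9])) == 0.5
        assert cd.decoding_agreement(np.array([3, 3]), np.array([3, 3])) == 1.0
        # one bin off everywhere counts zero (exact-match metric)
        assert cd.decoding_agreement(np.array([1, 2, 3]),
                                     np.array([0, 1, 2])) == 0.0

    def test_error_center_arithmetic(self):
        centers = np.arange(34, dtype=float)[:, None] * 3.0 + 1.5
        err, mean, med = cd.decoding_error(np.array([21]), np.array([19]), centers)
        assert err[0] == pytest.approx(6.0)       # 64.5 vs 58.5 cm
        centers2 = np.array([[1.5, 1.5], [4.5, 5.5]])
        err2, _, _ = cd.decoding_error(np.array([0]), np.array([1]), centers2)
        assert err2[0] == pytest.approx(5.0)      # 3-4-5 triangle

    def test_error_skips_undecodable(self):
        centers = np.array([[0.0], [1.0]])
        err, mean, med = cd.decoding_error(np.array([EXCLUDED, 1]),
                                           np.array([0, 1]), centers)
        assert np.isnan(err[0]) and err[1] == 0.0 and mean == 0.0

    def test_confusion_matrix(self):
        conf = cd.confusion_matrix(np.array([0, 0, 1, 2]),
                                   np.array([0, 1, 1, 2]), 4)
        np.testing.assert_allclose(conf[:, 0], [1, 0, 0, 0])
        np.testing.assert_allclose(conf[:, 1], [0.5, 0.5, 0, 0])
        assert conf[:, 3].sum() == 0.0            # unvisited column
        visited = conf.sum(axis=0) > 0
        np.testing.assert_allclose(conf[:, visited].sum(axis=0), 1.0)

    def test_always_zero_decoder(self):
        conf = cd.confusion_matrix(np.zeros(6, dtype=int),
                                   np.array([0, 1, 2, 0, 1, 2]), 3)
        np.testing.assert_allclose(conf[0], 1.0)

    def test_out_of_range_state(self):
        with pytest.raises(ValueError):
            cd.confusion_matrix(np.array([5]), np.array([0]), 3)


class TestSplitEpochs:
    def test_disjoint_and_sized(self):
        rng = np.random.default_rng(0)
        included = rng.random(3000) < 0.9
        splits = cd.split_epochs(3000, included, 0.5, block_s=5.0, rate=30.0,
                                 n_trials=5, seed=1)
        total = included.sum()
        for train, test in splits:
            assert not np.any(train & test)
            assert not np.any((train | test) & ~included)
            assert abs(train.sum() - 0.5 * total) <= 150   # one block
        # same seed reproduces the same split
        again = cd.split_epochs(3000, included, 0.5, 5.0, 30.0, 5, seed=1)
        np.testing.assert_array_equal(splits[0][0], again[0][0])

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            cd.split_epochs(100, np.ones(100, dtype=bool), 0.5,
                            block_s=10.0, rate=30.0)


class TestSweep:
    def test_result_shape(self, raster_spikes_1d, stateseq_1d):
        tab = cd.run_sweep(raster_spikes_1d, stateseq_1d,
                           {"window_s": [0.0, 0.25]}, n_trials=3, seed=0)
        assert len(tab) == 6
        assert set(tab["value"]) == {0.0, 0.25}

    def test_one_axis_only(self, raster_spikes_1d, stateseq_1d):
        with pytest.raises(ValueError):
            cd.run_sweep(raster_spikes_1d, stateseq_1d,
                         {"window_s": [0.0], "n_cells": [5]})
        with pytest.raises(ValueError):
            cd.run_sweep(raster_spikes_1d, stateseq_1d, {"window_s": []})

    def test_full_noise_is_chance_level(self, raster_spikes_1d, stateseq_1d):
        """Fully randomized tuning curves decode no better than a uniform
        random posterior."""
        tab = cd.run_sweep(raster_spikes_1d, stateseq_1d,
                           {"noise_fraction": [1.0]}, n_trials=5, seed=2)
        m = stateseq_1d.n_states
        centers = stateseq_1d.centers[:, 0]
        # chance-level oracle: decoded state uniform, actual from occupancy
        occ = stateseq_1d.occupancy() / stateseq_1d.occupancy().sum()
        chance = np.mean(np.abs(centers[:, None] - centers[None, :]) @ occ)
        assert abs(tab["mean_error_cm"].mean() - chance) < 0.2 * chance
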