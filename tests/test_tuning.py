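"""Tuning-curve estimation, Bayes consistency, MI, and perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import caldecode as cd
from caldecode.core import BinaryRaster
from conftest import make_stateseq


@pytest.fixture
def worked_example():
    """S = five frames in state 0 then five in state 1; A active 1,2,10."""
    seq = make_stateseq([0] * 5 + [1] * 5, 2)
    raster = BinaryRaster(np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 1]]), 30.0)
    return raster, seq


class TestEstimateTuning:
    def test_worked_example_counts(self, worked_example):
        raster, seq = worked_example
        m = cd.estimate_tuning(raster, seq)[0]
        assert m.marginal == pytest.approx(0.3)
        np.testing.assert_allclose(m.prior, [0.5, 0.5])
        np.testing.assert_allclose(m.joint[1], [0.2, 0.1])
        np.testing.assert_allclose(m.likelihood, [0.4, 0.2])

    def test_restricted_mask_counts(self, worked_example):
        raster, seq = worked_example
        mask = np.ones(10, dtype=bool)
        mask[:5] = False
        m = cd.estimate_tuning(raster, seq.restrict(mask))[0]
        np.testing.assert_allclose(m.prior, [0.0, 1.0])
        assert np.isnan(m.likelihood[0])       # state 0 never visited
        assert m.likelihood[1] == pytest.approx(0.2)

    def test_always_active(self, worked_example):
        _, seq = worked_example
        raster = BinaryRaster(np.ones((1, 10)), 30.0)
        m = cd.estimate_tuning(raster, seq)[0]
        np.testing.assert_allclose(m.likelihood, [1.0, 1.0])

    def test_no_included_frames_rejected(self, worked_example):
        raster, seq = worked_example
        with pytest.raises(ValueError):
            cd.estimate_tuning(raster, seq.restrict(np.zeros(10, dtype=bool)))


class TestPosterior:
    def test_worked_example_bayes(self, worked_example):
        raster, seq = worked_example
        m = cd.estimate_tuning(raster, seq)[0]
        np.testing.assert_allclose(cd.posterior_from_tuning(m), [2 / 3, 1 / 3])

    def test_flat_likelihood_returns_prior(self, worked_example):
        _, seq = worked_example
        m = cd.estimate_tuning(BinaryRaster(np.ones((1, 10)), 30.0), seq)[0]
        np.testing.assert_allclose(cd.posterior_from_tuning(m), m.prior)

    def test_never_active_undefined(self, worked_example):
        _, seq = worked_example
        m = cd.estimate_tuning(BinaryRaster(np.zeros((1, 10)), 30.0), seq)[0]
        assert np.isnan(cd.posterior_from_tuning(m)).all()

    def test_sums_to_one_on_synthetic_neurons(self, raster_rise_1d, stateseq_1d):
        for m in cd.estimate_tuning(raster_rise_1d, stateseq_1d):
            if m.marginal > 0:
                assert abs(cd.posterior_from_tuning(m).sum() - 1.0) < 1e-12


class TestMutualInfo:
    def test_independent_is_zero(self):
        ps = np.array([0.3, 0.5, 0.2])
        pa = np.array([0.8, 0.2])
        assert cd.mutual_info_from_joint(np.outer(pa, ps)) == pytest.approx(0.0, abs=1e-15)

    def test_perfectly_informative_is_one_bit(self):
        # two equiprobable states, active in state 0 only
        joint = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert cd.mutual_info_from_joint(joint) == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_entropy_identity(self, seed):
        """MI = H(S) + H(A) - H(S,A) — independent entropy oracle."""
        rng = np.random.default_rng(seed)
        joint = rng.random((2, rng.integers(2, 20)))
        joint /= joint.sum()

        def entropy(p):
            p = p[p > 0]
            return -np.sum(p * np.log2(p))

        oracle = (entropy(joint.sum(axis=0)) + entropy(joint.sum(axis=1))
                  - entropy(joint.ravel()))
        assert abs(cd.mutual_info_from_joint(joint) - oracle) < 1e-12

    def test_mi_bounds(self, raster_rise_1d, stateseq_1d):
        def entropy(p):
            p = p[p > 0]
            return -np.sum(p * np.log2(p))

        for m in cd.estimate_tuning(raster_rise_1d, stateseq_1d)[:10]:
            hs = entropy(m.prior)
            ha = entropy(np.array([1 - m.marginal, m.marginal]))
            assert -1e-12 <= m.mi_bits <= min(hs, ha) + 1e-12

    def test_mi_ranks_by_field_contrast(self, session_1d, stateseq_1d):
        """Cells with a larger peak/baseline contrast carry more bits."""
        track = session_1d.track
        p_maxes = np.linspace(0.03, 0.5, 60)
        rng = np.random.default_rng(0)
        mis = []
        for p in p_maxes:
            spikes, _ = cd.simulate_place_cells(track, 1, p_max=p,
                                                baseline=0.01, seed=rng)
            raster = cd.binarize_from_deconvolved(spikes, 30.0)
            mis.append(cd.estimate_tuning(raster, stateseq_1d)[0].mi_bits)
        rho, _ = spearmanr(p_maxes, mis)
        assert rho > 0.8


class TestSmoothing:
    def test_sigma_zero_identity(self, worked_example):
        raster, seq = worked_example
        m = cd.estimate_tuning(raster, seq)[0]
        np.testing.assert_array_equal(cd.smooth_tuning(m, 0.0).likelihood,
                                      m.likelihood)

    def test_negative_sigma_rejected(self, worked_example):
        raster, seq = worked_example
        with pytest.raises(ValueError):
            cd.smooth_tuning(cd.estimate_tuning(raster, seq)[0], -1.0)

    def test_interior_delta_mass_preserved(self):
        # kernel support (+/- 4 sigma) stays clear of both boundaries
        m = _model_with_likelihood(np.eye(21)[10])
        assert cd.smooth_tuning(m, 1.0).likelihood.sum() == pytest.approx(1.0)

    def test_constant_curve_fixed_point(self):
        m = _model_with_likelihood(np.full(15, 0.37))
        for sigma in (0.5, 1.0, 3.0):
            np.testing.assert_allclose(cd.smooth_tuning(m, sigma).likelihood, 0.37)

    def test_2d_smoothing_on_grid(self):
        lik = np.zeros(25)
        lik[12] = 1.0
        m = _model_with_likelihood(lik, grid_shape=(5, 5))
        sm = cd.smooth_tuning(m, 1.0).likelihood.reshape(5, 5)
        assert sm[2, 2] == sm.max()
        assert sm[2, 1] == pytest.approx(sm[1, 2])


class TestInjectNoise:
    def test_identity_and_full_replacement(self):
        m = _model_with_likelihood(np.linspace(0, 1, 34))
        np.testing.assert_array_equal(cd.inject_noise(m, 0.0, 0).likelihood,
                                      m.likelihood)
        replaced = cd.inject_noise(m, 1.0, 0).likelihood
        assert np.sum(replaced != m.likelihood) == 34

    def test_half_replacement_count(self):
        m = _model_with_likelihood(np.linspace(1.5, 2.5, 34) / 10.0)
        out = cd.inject_noise(m, 0.5, seed=7).likelihood
        assert np.sum(out != m.likelihood) == 17

    def test_fraction_out_of_range(self):
        m = _model_with_likelihood(np.zeros(5))
        with pytest.raises(ValueError):
            cd.inject_noise(m, 1.5, 0)


def _model_with_likelihood(lik, grid_shape=None):
    lik = np.asarray(lik, dtype=float)
    m = lik.size
    return cd.TuningModel(marginal=0.1, prior=np.full(m, 1 / m),
                          joint=np.zeros((2, m)), likelihood=lik,
                          occupancy=np.ones(m, dtype=int), mi_bits=0.0,
                          grid_shape=grid_shape)
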