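"""Probabilistic tuning curves and mutual information.

For a binarized neuron A and a discrete behavioral state sequence S with
M states, all estimates are plain frame counts over included frames:

* marginal  P(A)        — fraction of frames active,
* prior     P(S_i)      — fraction of frames in state i (occupancy),
* joint     P(S_i & A_j) — 2 x M table over j in {inactive, active},
* likelihood P(A|S_i)   — the tuning curve,
* posterior P(S_i|A)    — Bayes: likelihood x prior / marginal,
* mutual information    — bits shared between activity and state.

States never visited carry NaN ("undefined") in the likelihood rather
than 0: zero would claim certain silence where there is simply no data.
Downstream operations (MI, decoding, smoothing) skip undefined states.

Two perturbations used in decoder robustness sweeps live here as well:
replacement of a fraction of tuning-curve entries by uniform random
values, and Gaussian smoothing of the curve/map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .core import BinaryRaster, StateSequence, _as_rng

logger = logging.getLogger(__name__)


@dataclass
class TuningModel:
    """Per-neuron probabilistic tuning estimates (all frame-count based)."""

    marginal: float                 # P(A)
    prior: np.ndarray               # P(S), length M
    joint: np.ndarray               # (2, M): row 0 inactive, row 1 active
    likelihood: np.ndarray          # P(A|S), NaN where occupancy is zero
    occupancy: np.ndarray           # frame counts per state
    mi_bits: float
    centers: Optional[np.ndarray] = None   # state geometry (cm), for errors
    grid_shape: Optional[tuple] = None     # (ny, nx) when states form a 2D grid

    @property
    def n_states(self) -> int:
        return self.prior.shape[0]


def mutual_info_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a 2 x M joint table, with the 0*log(0) := 0 convention."""
    joint = np.asarray(joint, dtype=float)
    pa = joint.sum(axis=1, keepdims=True)    # P(A_j)
    ps = joint.sum(axis=0, keepdims=True)    # P(S_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pa * ps))
    return float(np.nansum(np.where(joint > 0, terms, 0.0)))


def estimate_tuning(raster: BinaryRaster, stateseq: StateSequence) -> List[TuningModel]:
    """Estimate one :class:`TuningModel` per neuron by frame counting.

    Only included frames contribute.  States with zero occupancy get a
    NaN likelihood and are excluded from MI and decoding.
    """
    if raster.n_frames != stateseq.n_frames:
        raise ValueError("raster and state sequence must share a frame clock")
    inc = stateseq.included_mask
    total = int(inc.sum())
    if total == 0:
        raise ValueError("no included frames")
    m = stateseq.n_states
    s = stateseq.state_id[inc]
    act = raster.states[:, inc].astype(float)        # (N, T_inc)
    occ = np.bincount(s, minlength=m)                # frames per state
    onehot = np.zeros((total, m))
    onehot[np.arange(total), s] = 1.0
    active_counts = act @ onehot                      # (N, M)
    prior = occ / total
    models = []
    for k in range(raster.n_neurons):
        joint_active = active_counts[k] / total
        joint = np.vstack([prior - joint_active, joint_active])
        lik = np.where(occ > 0, active_counts[k] / np.maximum(occ, 1), np.nan)
        marginal = float(act[k].mean())
        models.append(TuningModel(
            marginal=marginal, prior=prior, joint=joint, likelihood=lik,
            occupancy=occ, mi_bits=mutual_info_from_joint(joint),
            centers=stateseq.centers, grid_shape=stateseq.grid_shape))
    return models


def likelihood_curve(raster_row: np.ndarray, stateseq: StateSequence) -> np.ndarray:
    """Fast path: P(A|S) for one activity vector (NaN where unvisited).

    Used heavily by the shuffling and bootstrap machinery, where the full
    :class:`TuningModel` would be wasteful.
    """
    inc = stateseq.included_mask
    s = stateseq.state_id[inc]
    a = np.asarray(raster_row, dtype=bool)[inc]
    m = stateseq.n_states
    occ = np.bincount(s, minlength=m)
    active = np.bincount(s[a], minlength=m)
    with np.errstate(invalid="ignore"):
        return np.where(occ > 0, active / np.maximum(occ, 1), np.nan)


def joint_table(raster_row: np.ndarray, stateseq: StateSequence) -> np.ndarray:
    """2 x M joint probability table for one activity vector."""
    inc = stateseq.included_mask
    s = stateseq.state_id[inc]
    a = np.asarray(raster_row, dtype=bool)[inc]
    m = stateseq.n_states
    total = s.shape[0]
    occ = np.bincount(s, minlength=m) / total
    joint_active = np.bincount(s[a], minlength=m) / total
    return np.vstack([occ - joint_active, joint_active])


def posterior_from_tuning(model: TuningModel) -> np.ndarray:
    """Posterior P(S|A) = P(A|S) * P(S) / P(A); NaN states contribute 0.

    For a never-active neuron (marginal 0) the posterior is undefined:
    an all-NaN vector is returned with a logged warning.
    """
    if model.marginal == 0:
        logger.warning("never-active neuron: posterior undefined")
        return np.full(model.n_states, np.nan)
    lik = np.where(np.isnan(model.likelihood), 0.0, model.likelihood)
    return lik * model.prior / model.marginal


def mutual_info(model: TuningModel) -> float:
    """MI in bits between binary activity and state (from the joint table)."""
    return mutual_info_from_joint(model.joint)


def _gaussian_kernel(sigma: float) -> np.ndarray:
    radius = int(np.ceil(4 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-x * x / (2.0 * sigma * sigma))
    return k / k.sum()


def _nan_smooth(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that renormalizes over defined (non-NaN) bins."""
    from scipy.ndimage import convolve

    k1 = _gaussian_kernel(sigma)
    kern = k1 if values.ndim == 1 else np.outer(k1, k1)
    defined = ~np.isnan(values)
    filled = np.where(defined, values, 0.0)
    num = convolve(filled, kern, mode="constant", cval=0.0)
    den = convolve(defined.astype(float), kern, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~defined] = np.nan
    return out


def smooth_tuning(model: TuningModel, sigma_bins: float) -> TuningModel:
    """Gaussian-smooth the tuning curve (1D) or map (2D grid).

    The kernel is truncated at +/- 4 sigma and renormalized over defined
    bins at boundaries (no wraparound — tracks are not circular).
    ``sigma_bins = 0`` is the identity.
    """
    if sigma_bins < 0:
        raise ValueError("sigma_bins must be >= 0")
    if sigma_bins == 0:
        return replace(model)
    lik = model.likelihood
    if model.grid_shape is not None:
        sm = _nan_smooth(lik.reshape(model.grid_shape), sigma_bins).ravel()
    else:
        sm = _nan_smooth(lik, sigma_bins)
    return replace(model, likelihood=sm)


def inject_noise(model: TuningModel, fraction: float, seed=None) -> TuningModel:
    """Replace a fraction of tuning-curve entries by Uniform(0,1) draws.

    Exactly ``round(fraction * M_defined)`` defined likelihood entries,
    chosen uniformly without replacement, are replaced; prior and
    marginal are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = _as_rng(seed)
    lik = model.likelihood.copy()
    defined = np.flatnonzero(~np.isnan(lik))
    n_replace = int(round(fraction * defined.size))
    if n_replace > 0:
        idx = rng.choice(defined, size=n_replace, replace=False)
        lik[idx] = rng.uniform(0.0, 1.0, size=n_replace)
    return replace(model, likelihood=lik)
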