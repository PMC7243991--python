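"""Naive Bayes decoding of behavioral state from binary population activity.

For neurons k = 1..N with tuning curves P(A_k|S), the posterior over
states given the set of neurons active at frame t is, under neuron
independence,

    P(S | A_t)  ∝  Π_{k active} P(A_k|S) · P(S) / P(A_k).

Products of many probabilities underflow, so scoring is done in log
space.  Two variants are provided:

* ``log_product`` (default) — sums log P(A_k|S) + log P(S) - log P(A_k)
  per active neuron, with -inf for zero likelihood (a zero means the
  neuron was never active in that state during training, i.e. certainty
  the animal is not there).  Its MAP state is exactly the linear-product
  MAP.
* ``log1p`` — sums log(1 + P(A_k|S)·P(S)/P(A_k)), a softened
  variant that avoids -inf; it is *not* order-equivalent to the product
  and is kept as a separate, documented scoring rule.

Temporal filtering pools the per-frame log scores over the past L frames
(inclusive of the current one), suppressing erratic frame-to-frame jumps
in the decoded trajectory.

The decoded state is the maximum a posteriori (argmax); accuracy is
summarized by decoding agreement (exact-state fraction), decoding error
(Euclidean distance between decoded and actual bin centers, in cm), and
the confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import EXCLUDED, BinaryRaster, StateSequence, _as_rng
from . import tuning as _tuning

logger = logging.getLogger(__name__)

PRIOR_MODES = ("uniform", "observed", "unbiased")
SCORING_VARIANTS = ("log_product", "log1p")


@dataclass
class DecoderModel:
    """Fitted tuning curves plus the prior/bias configuration for decoding."""

    likelihood: np.ndarray        # (N, M) P(A_k|S) on retained states
    marginal: np.ndarray          # (N,) P(A_k); all ones in unbiased mode
    prior: np.ndarray             # (M,) decoding prior
    observed_prior: np.ndarray    # (M,) empirical occupancy P(S)
    prior_mode: str
    scoring_variant: str
    state_ids: np.ndarray         # retained original state ids
    centers: np.ndarray           # (M, ndim) retained bin centers, cm
    neuron_ids: np.ndarray        # retained neuron indices in the raster
    sampling_rate: float
    n_states_full: int = 0        # state count before zero-occupancy removal
    grid_shape: Optional[tuple] = None
    use_inactive_evidence: bool = False

    @property
    def n_neurons(self) -> int:
        return self.likelihood.shape[0]

    @property
    def n_states(self) -> int:
        return self.likelihood.shape[1]


@dataclass
class PosteriorTrajectory:
    """Frame-wise posteriors and MAP states from one decoding pass."""

    posteriors: np.ndarray        # (T, M) rows sum to 1 on decodable frames
    map_state: np.ndarray         # (T,) retained-space argmax, EXCLUDED if undecodable
    decodable: np.ndarray         # (T,) bool: any evidence in the window
    window_frames: int
    n_active_per_frame: np.ndarray
    model: DecoderModel

    @property
    def map_state_original(self) -> np.ndarray:
        """MAP states mapped back to the training state geometry ids."""
        out = np.full(self.map_state.shape, EXCLUDED, dtype=np.int64)
        ok = self.map_state != EXCLUDED
        out[ok] = self.model.state_ids[self.map_state[ok]]
        return out


@dataclass
class DecodingReport:
    agreement: float
    mean_error_cm: float
    median_error_cm: float
    error_per_frame_cm: np.ndarray
    confusion: np.ndarray
    n_frames_scored: int
    n_undecodable: int


def build_decoder(raster_train: BinaryRaster, stateseq_train: StateSequence,
                  prior_mode: str = "uniform",
                  scoring_variant: str = "log_product",
                  use_inactive_evidence: bool = False) -> DecoderModel:
    """Fit per-neuron tuning on training frames and assemble a decoder.

    States with zero training occupancy are removed from the decode
    state space; neurons never active in training are dropped with a
    warning.  ``prior_mode``:

    * ``uniform``  — flat prior over retained states,
    * ``observed`` — empirical occupancy prior,
    * ``unbiased`` — flat prior with the per-neuron marginal P(A_k)
      replaced by 1 (a "bias removal" ablation; it only changes the
      MAP under the log1p scoring rule).
    """
    if prior_mode not in PRIOR_MODES:
        raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
    if scoring_variant not in SCORING_VARIANTS:
        raise ValueError(f"scoring_variant must be one of {SCORING_VARIANTS}")
    models = _tuning.estimate_tuning(raster_train, stateseq_train)
    marginal = np.array([m.marginal for m in models])
    keep_n = marginal > 0
    if not keep_n.any():
        raise ValueError("no neuron is active in the training frames")
    if (~keep_n).any():
        logger.warning("dropping %d neuron(s) silent in training", (~keep_n).sum())
    occ = models[0].occupancy
    keep_s = occ > 0
    state_ids = np.flatnonzero(keep_s)
    lik = np.array([m.likelihood for m in models])[keep_n][:, keep_s]
    observed_prior = occ[keep_s] / occ[keep_s].sum()
    m_ret = keep_s.sum()
    if prior_mode == "observed":
        prior = observed_prior.copy()
    else:
        prior = np.full(m_ret, 1.0 / m_ret)
    marg = marginal[keep_n]
    if prior_mode == "unbiased":
        marg = np.ones_like(marg)
    return DecoderModel(
        likelihood=lik, marginal=marg, prior=prior,
        observed_prior=observed_prior, prior_mode=prior_mode,
        scoring_variant=scoring_variant, state_ids=state_ids,
        centers=stateseq_train.centers[keep_s],
        neuron_ids=np.flatnonzero(keep_n),
        sampling_rate=raster_train.sampling_rate,
        n_states_full=stateseq_train.n_states,
        grid_shape=stateseq_train.grid_shape,
        use_inactive_evidence=use_inactive_evidence)


def _log_scores(active: np.ndarray, model: DecoderModel) -> np.ndarray:
    """Per-frame, per-state log evidence; (T, M)."""
    a = active.astype(float).T                       # (T, N)
    with np.errstate(divide="ignore"):
        if model.scoring_variant == "log_product":
            log_lik = np.log(model.likelihood)       # -inf on zeros
            log_prior = np.log(model.prior)
            per_neuron = log_lik - np.log(model.marginal)[:, None]
            # -inf * 0 would be NaN through matmul; route zeros explicitly
            scores = _masked_matmul(a, per_neuron)
            scores += a.sum(axis=1)[:, None] * log_prior[None, :]
            if model.use_inactive_evidence:
                log_inact = np.log1p(-model.likelihood)
                scores += _masked_matmul(1.0 - a, log_inact)
        else:  # log1p
            w = np.log1p(model.likelihood * model.prior[None, :]
                         / model.marginal[:, None])
            scores = a @ w
    return scores


def _masked_matmul(weights: np.ndarray, terms: np.ndarray) -> np.ndarray:
    """weights @ terms where terms may hold -inf but weights are 0/1."""
    finite = np.isfinite(terms)
    safe = np.where(finite, terms, 0.0)
    out = weights @ safe
    hit_inf = weights @ (~finite).astype(float) > 0
    out[hit_inf] = -np.inf
    return out


def decode_posteriors(raster_test: BinaryRaster, model: DecoderModel,
                      window_s: float = 0.0) -> PosteriorTrajectory:
    """Decode a posterior over states for every frame of a test raster.

    Evidence comes from neurons *active* at each frame (optionally also
    inactive neurons via 1 - P(A_k|S)).  With ``window_s > 0`` the
    per-frame log scores are summed over the past L = round(window_s *
    rate) frames, current frame included.  Frames with no active neuron
    in the window are undecodable: their posterior falls back to the
    prior and their MAP state is flagged.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    active = raster_test.states[model.neuron_ids].astype(bool)
    t = active.shape[1]
    scores = _log_scores(active, model)
    n_active = active.sum(axis=0)
    window = max(1, int(round(window_s * model.sampling_rate)))
    if window > 1:
        scores = _trailing_sum(scores, window)
        n_evidence = _trailing_sum(n_active[:, None].astype(float), window)[:, 0]
    else:
        n_evidence = n_active.astype(float)
    decodable = n_evidence > 0
    posteriors = np.tile(model.prior, (t, 1))
    if decodable.any():
        sc = scores[decodable]
        peak = sc.max(axis=1, keepdims=True)
        # frames where every state scored -inf stay undecodable
        all_dead = ~np.isfinite(peak[:, 0])
        with np.errstate(invalid="ignore"):
            p = np.exp(sc - peak)
        p[all_dead] = np.nan
        norm = p.sum(axis=1, keepdims=True)
        p = np.where(np.isnan(p), 0.0, p / norm)
        p[all_dead] = model.prior
        posteriors[decodable] = p
        idx = np.flatnonzero(decodable)
        decodable = decodable.copy()
        decodable[idx[all_dead]] = False
    n_undec = int((~decodable).sum())
    if n_undec:
        logger.info("%d undecodable frame(s): posterior falls back to prior", n_undec)
    map_state = np.full(t, EXCLUDED, dtype=np.int64)
    map_state[decodable] = np.argmax(posteriors[decodable], axis=1)
    return PosteriorTrajectory(posteriors, map_state, decodable, window,
                               n_active, model)


def _trailing_sum(x: np.ndarray, window: int) -> np.ndarray:
    """Sum over the past ``window`` rows inclusive (partial at the start)."""
    finite = np.isfinite(x)
    safe = np.where(finite, x, 0.0)
    c = np.cumsum(safe, axis=0)
    out = c.copy()
    out[window:] = c[window:] - c[:-window]
    cinf = np.cumsum(~finite, axis=0)
    ninf = cinf.copy()
    ninf[window:] = cinf[window:] - cinf[:-window]
    out[ninf > 0] = -np.inf
    return out


def map_estimate(posteriors: np.ndarray) -> np.ndarray:
    """Argmax state per frame; ties break to the lowest index.

    All-NaN rows yield the EXCLUDED marker.
    """
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    out = np.full(posteriors.shape[0], EXCLUDED, dtype=np.int64)
    valid = ~np.isnan(posteriors).all(axis=1)
    filled = np.where(np.isnan(posteriors), -np.inf, posteriors)
    out[valid] = np.argmax(filled[valid], axis=1)
    return out


def decoding_agreement(decoded: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of scorable frames where the exact state was decoded.

    Frames where either vector carries the EXCLUDED marker are dropped.
    """
    decoded = np.asarray(decoded)
    actual = np.asarray(actual)
    if decoded.shape != actual.shape:
        raise ValueError("decoded and actual must be aligned")
    ok = (decoded != EXCLUDED) & (actual != EXCLUDED)
    if not ok.any():
        raise ValueError("no decodable frames to score")
    return float(np.mean(decoded[ok] == actual[ok]))


def decoding_error(decoded: np.ndarray, actual: np.ndarray,
                   centers: np.ndarray) -> Tuple[np.ndarray, float, float]:
    """Euclidean distance (cm) between decoded and actual bin centers.

    Returns (per-frame error with NaN on unscorable frames, mean, median).
    """
    decoded = np.asarray(decoded)
    actual = np.asarray(actual)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    ok = (decoded != EXCLUDED) & (actual != EXCLUDED)
    err = np.full(decoded.shape, np.nan)
    d = centers[decoded[ok]] - centers[actual[ok]]
    err[ok] = np.linalg.norm(d, axis=1)
    if not ok.any():
        return err, np.nan, np.nan
    return err, float(np.nanmean(err)), float(np.nanmedian(err))


def confusion_matrix(decoded: np.ndarray, actual: np.ndarray, n_states: int) -> np.ndarray:
    """M x M matrix: entry (d, a) = fraction of actual-a frames decoded d.

    Visited columns sum to 1; unvisited columns are all zero.
    """
    decoded = np.asarray(decoded)
    actual = np.asarray(actual)
    ok = (decoded != EXCLUDED) & (actual != EXCLUDED)
    d, a = decoded[ok], actual[ok]
    if ok.any() and (d.max() >= n_states or a.max() >= n_states):
        raise ValueError("state out of range")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (d, a), 1.0)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(col > 0, counts / col, 0.0)
    return out


def split_epochs(n_frames: int, included_mask: np.ndarray,
                 train_fraction: float = 0.5, block_s: float = 5.0,
                 rate: float = 30.0, n_trials: int = 1,
                 seed=None) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Random non-overlapping train/test epoch splits.

    The session is cut into contiguous blocks of ``block_s`` seconds
    (long enough to preserve transient structure); blocks are assigned
    to training at random until the included-frame fraction reaches
    ``train_fraction``, the remainder to test.  Excluded frames belong
    to neither mask.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    included_mask = np.asarray(included_mask, dtype=bool)
    block_len = max(1, int(round(block_s * rate)))
    n_blocks = int(np.ceil(n_frames / block_len))
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks to split")
    rng = _as_rng(seed)
    block_of = np.minimum(np.arange(n_frames) // block_len, n_blocks - 1)
    inc_per_block = np.bincount(block_of[included_mask], minlength=n_blocks)
    total_inc = inc_per_block.sum()
    splits = []
    for _ in range(n_trials):
        order = rng.permutation(n_blocks)
        train_blocks = np.zeros(n_blocks, dtype=bool)
        acc = 0
        for b in order:
            if acc >= train_fraction * total_inc:
                break
            train_blocks[b] = True
            acc += inc_per_block[b]
        train_mask = train_blocks[block_of] & included_mask
        test_mask = ~train_blocks[block_of] & included_mask
        splits.append((train_mask, test_mask))
    return splits


def evaluate_decoding(traj: PosteriorTrajectory, stateseq: StateSequence,
                      test_mask: Optional[np.ndarray] = None,
                      undecodable: str = "exclude") -> DecodingReport:
    """Score a decoded trajectory against the actual state sequence.

    Undecodable frames (no evidence in the window) are by default
    excluded from the metrics but counted in the report; with
    ``undecodable="count"`` they are scored from the fallback posterior
    (the prior, argmax with lowest-index ties), which penalizes decoders
    that leave many frames without evidence.  Actual states are mapped
    into the decoder's retained state space; test frames in states
    unseen during training are unscorable either way.
    """
    model = traj.model
    t = traj.posteriors.shape[0]
    if stateseq.n_frames != t:
        raise ValueError("state sequence and trajectory must be aligned")
    scope = stateseq.included_mask.copy()
    if test_mask is not None:
        scope &= np.asarray(test_mask, dtype=bool)
    # map actual original-space states into the retained decode space
    inv = np.full(stateseq.n_states, EXCLUDED, dtype=np.int64)
    inv[model.state_ids] = np.arange(model.n_states)
    actual = np.full(t, EXCLUDED, dtype=np.int64)
    actual[scope] = inv[stateseq.state_id[scope]]
    if undecodable not in ("exclude", "count"):
        raise ValueError("undecodable must be 'exclude' or 'count'")
    decoded = traj.map_state.copy()
    if undecodable == "count":
        fallback = ~traj.decodable & scope
        decoded[fallback] = np.argmax(traj.posteriors[fallback], axis=1)
    decoded[~scope] = EXCLUDED
    n_undec = int((scope & ~traj.decodable).sum())
    agreement = decoding_agreement(decoded, actual)
    err, mean_err, med_err = decoding_error(decoded, actual, model.centers)
    conf = confusion_matrix(decoded, actual, model.n_states)
    scored = int(((decoded != EXCLUDED) & (actual != EXCLUDED)).sum())
    return DecodingReport(agreement, mean_err, med_err, err, conf,
                          scored, n_undec)


def train_test_decode(raster: BinaryRaster, stateseq: StateSequence,
                      train_mask: np.ndarray, test_mask: np.ndarray,
                      prior_mode: str = "uniform",
                      scoring_variant: str = "log_product",
                      window_s: float = 0.0,
                      neuron_subset: Optional[np.ndarray] = None,
                      noise_fraction: float = 0.0,
                      smooth_sigma: float = 0.0,
                      undecodable: str = "exclude",
                      seed=None) -> DecodingReport:
    """One full train/decode/score pass, with optional model perturbations."""
    rng = _as_rng(seed)
    if neuron_subset is not None:
        raster = BinaryRaster(raster.states[neuron_subset], raster.sampling_rate,
                              raster.method, raster.parameters)
    model = build_decoder(raster, stateseq.restrict(train_mask),
                          prior_mode, scoring_variant)
    if noise_fraction > 0 or smooth_sigma > 0:
        model.likelihood = perturb_likelihoods(model, noise_fraction,
                                               smooth_sigma, rng)
    traj = decode_posteriors(raster, model, window_s)
    return evaluate_decoding(traj, stateseq, test_mask, undecodable)


def perturb_likelihoods(model: DecoderModel, noise_fraction: float,
                        smooth_sigma: float, rng) -> np.ndarray:
    """Noise-inject and/or smooth each neuron's fitted tuning curve.

    Perturbations are applied on the full training state geometry (so 2D
    maps smooth on their grid), then restricted back to retained states.
    """
    lik = model.likelihood.copy()
    occ = np.zeros(model.n_states_full, dtype=int)
    occ[model.state_ids] = 1
    for k in range(lik.shape[0]):
        full = np.full(model.n_states_full, np.nan)
        full[model.state_ids] = lik[k]
        tm = _tuning.TuningModel(model.marginal[k], occ / occ.sum(),
                                 np.zeros((2, model.n_states_full)), full,
                                 occ, np.nan, None, model.grid_shape)
        if noise_fraction > 0:
            tm = _tuning.inject_noise(tm, noise_fraction, rng)
        if smooth_sigma > 0:
            tm = _tuning.smooth_tuning(tm, smooth_sigma)
        lik[k] = tm.likelihood[model.state_ids]
    return lik


SWEEP_AXES = ("window_s", "n_cells", "train_fraction", "noise_fraction",
              "smooth_sigma")


def run_sweep(raster: BinaryRaster, stateseq: StateSequence, grid: dict,
              n_trials: int = 30, train_fraction: float = 0.5,
              block_s: float = 5.0, window_s: float = 0.0,
              prior_mode: str = "uniform",
              scoring_variant: str = "log_product",
              undecodable: str = "exclude",
              seed=None) -> pd.DataFrame:
    """Decoding-accuracy sweep along exactly one parameter axis.

    ``grid`` maps one of ``window_s | n_cells | train_fraction |
    noise_fraction | smooth_sigma`` to a list of values.  Each grid value
    is evaluated on ``n_trials`` independent epoch splits (fresh split,
    build, decode); cell subsets are drawn at random per trial; noise and
    smoothing perturb the trained tuning curves before decoding.
    Returns a tidy table with one row per (value, trial).
    """
    if len(grid) != 1:
        raise ValueError("exactly one grid axis must vary per sweep")
    axis, values = next(iter(grid.items()))
    if axis not in SWEEP_AXES:
        raise ValueError(f"grid axis must be one of {SWEEP_AXES}")
    if len(values) == 0:
        raise ValueError("empty grid")
    rng = _as_rng(seed)
    rows = []
    for value in values:
        params = dict(window_s=window_s, train_fraction=train_fraction,
                      noise_fraction=0.0, smooth_sigma=0.0)
        n_cells = None
        if axis == "n_cells":
            n_cells = int(value)
        else:
            params[axis] = value
        splits = split_epochs(raster.n_frames, stateseq.included_mask,
                              params["train_fraction"], block_s,
                              raster.sampling_rate, n_trials, rng)
        for trial, (train_mask, test_mask) in enumerate(splits):
            subset = None
            if n_cells is not None:
                subset = rng.choice(raster.n_neurons, size=n_cells, replace=False)
            rep = train_test_decode(
                raster, stateseq, train_mask, test_mask, prior_mode,
                scoring_variant, params["window_s"], subset,
                params["noise_fraction"], params["smooth_sigma"],
                undecodable, rng)
            rows.append({"axis": axis, "value": value, "trial": trial,
                         "agreement": rep.agreement,
                         "mean_error_cm": rep.mean_error_cm,
                         "median_error_cm": rep.median_error_cm})
    return pd.DataFrame(rows)
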