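"""Null-hypothesis testing and confidence intervals for tuning estimates.

Significance uses *circular permutations*: the binary activity vector is
rotated in time by a random shift, which destroys its relationship to
behavior while preserving the temporal structure of transients — a more
conservative null than independently permuting frames.  Empirical
p-values count how many surrogate statistics exceed the actual one.

Confidence intervals use bootstrap resampling: the likelihood curve (or
MI) is recomputed on random half-size subsets of included frames drawn
with replacement, and percentile bands are reported.

Both resamplers are generic over the statistic (tuning curve or mutual
information) so the same code path serves place-field significance and
encoding-confidence analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .core import StateSequence, _as_rng
from .tuning import likelihood_curve, joint_table, mutual_info_from_joint

_STATISTICS = ("likelihood_curve", "mi")


def _statistic_fn(statistic: Union[str, Callable]) -> Callable:
    if callable(statistic):
        return statistic
    if statistic == "likelihood_curve":
        return likelihood_curve
    if statistic == "mi":
        return lambda row, seq: mutual_info_from_joint(joint_table(row, seq))
    raise ValueError(f"statistic must be one of {_STATISTICS} or a callable")


@dataclass
class ShuffleDistribution:
    statistic_name: str
    actual: np.ndarray        # (M,) for curves, scalar array for MI
    surrogates: np.ndarray    # (n_shuffles, M) or (n_shuffles,)
    shifts: np.ndarray        # (n_shuffles,) applied rotations

    @property
    def n_shuffles(self) -> int:
        return self.surrogates.shape[0]


@dataclass
class SignificanceResult:
    p_value: np.ndarray
    shuffled_mean: np.ndarray
    shuffled_sd: np.ndarray
    shuffled_sem: np.ndarray
    thresholded_likelihood: np.ndarray
    alpha: float


@dataclass
class BootstrapResult:
    samples: np.ndarray       # (n_boot, M) curves or (n_boot,) MI values
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    sample_fraction: float


def circular_shuffle_statistic(raster_row: np.ndarray, stateseq: StateSequence,
                               statistic: Union[str, Callable] = "likelihood_curve",
                               n_shuffles: int = 1000, seed=None) -> ShuffleDistribution:
    """Build a null distribution by circularly rotating the activity vector.

    Shifts are drawn uniformly from [1, T-1] (the identity rotation is
    excluded — it would only dilute the null).  Rotation happens in full
    frame space *before* the inclusion mask is applied, preserving
    transient structure, and the state sequence is untouched.
    """
    row = np.asarray(raster_row).ravel().astype(bool)
    t = row.shape[0]
    if t < 2:
        raise ValueError("need at least 2 frames to shuffle")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    fn = _statistic_fn(statistic)
    rng = _as_rng(seed)
    shifts = rng.integers(1, t, size=n_shuffles)
    actual = np.asarray(fn(row, stateseq), dtype=float)
    surrogates = np.empty((n_shuffles,) + actual.shape)
    for i, shift in enumerate(shifts):
        surrogates[i] = fn(np.roll(row, shift), stateseq)
    name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    return ShuffleDistribution(name, actual, surrogates, shifts)


def empirical_pvalue(actual: np.ndarray, surrogates: np.ndarray,
                     tie_mode: str = "strict") -> np.ndarray:
    """p = fraction of surrogates above the actual value.

    ``"strict"`` counts surrogates strictly greater (so p can be exactly
    0); ``"inclusive"`` counts ties as well, which is more conservative
    when surrogates frequently equal the actual value (e.g. empty bins).
    """
    actual = np.asarray(actual, dtype=float)
    surrogates = np.asarray(surrogates, dtype=float)
    if surrogates.shape[0] < 1 or surrogates.shape[1:] != actual.shape:
        raise ValueError("surrogates must be (n_shuffles,) + actual.shape")
    if tie_mode == "strict":
        above = surrogates > actual
    elif tie_mode == "inclusive":
        above = surrogates >= actual
    else:
        raise ValueError("tie_mode must be 'strict' or 'inclusive'")
    # NaN surrogate entries (states unvisited in a surrogate) never count
    return np.nansum(above, axis=0) / surrogates.shape[0]


def threshold_field(likelihood: np.ndarray, p_values: np.ndarray,
                    alpha: float = 0.05) -> np.ndarray:
    """Retain only significant entries; the rest become NaN (undefined)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    likelihood = np.asarray(likelihood, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if likelihood.shape != p_values.shape:
        raise ValueError("likelihood and p_values must be aligned")
    return np.where(p_values < alpha, likelihood, np.nan)


def tuning_significance(raster_row: np.ndarray, stateseq: StateSequence,
                        n_shuffles: int = 1000, alpha: float = 0.05,
                        tie_mode: str = "strict", seed=None) -> SignificanceResult:
    """Shuffle test of one tuning curve: p-values, null moments, thresholded field."""
    dist = circular_shuffle_statistic(raster_row, stateseq, "likelihood_curve",
                                      n_shuffles, seed)
    p = empirical_pvalue(dist.actual, dist.surrogates, tie_mode)
    mean = np.nanmean(dist.surrogates, axis=0)
    sd = np.nanstd(dist.surrogates, axis=0)
    n_eff = np.sum(~np.isnan(dist.surrogates), axis=0)
    sem = sd / np.sqrt(np.maximum(n_eff, 1))
    return SignificanceResult(p, mean, sd, sem,
                              threshold_field(dist.actual, p, alpha), alpha)


def bootstrap_statistic(raster_row: np.ndarray, stateseq: StateSequence,
                        statistic: Union[str, Callable] = "likelihood_curve",
                        n_boot: int = 1000, sample_fraction: float = 0.5,
                        level: float = 95.0, seed=None) -> BootstrapResult:
    """Percentile bootstrap of a tuning statistic over included frames.

    Each sample draws ``round(sample_fraction * T_included)`` included
    frames with replacement and recomputes the statistic on that subset.
    """
    if not 0.0 < sample_fraction <= 1.0:
        raise ValueError("sample_fraction must be in (0, 1]")
    if not 0.0 < level < 100.0:
        raise ValueError("level must be in (0, 100)")
    row = np.asarray(raster_row).ravel().astype(bool)
    inc_idx = np.flatnonzero(stateseq.included_mask)
    if inc_idx.size == 0:
        raise ValueError("no included frames")
    rng = _as_rng(seed)
    n_draw = max(1, int(round(sample_fraction * inc_idx.size)))
    m = stateseq.n_states
    s_inc = stateseq.state_id[inc_idx]
    a_inc = row[inc_idx]
    fn = statistic if callable(statistic) else None
    if fn is None and statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS} or a callable")
    first = _subset_statistic(statistic, fn, a_inc, s_inc, m,
                              np.arange(inc_idx.size))
    samples = np.empty((n_boot,) + np.shape(first))
    for i in range(n_boot):
        pick = rng.integers(0, inc_idx.size, size=n_draw)
        samples[i] = _subset_statistic(statistic, fn, a_inc, s_inc, m, pick)
    lo, hi = (100.0 - level) / 2.0, 100.0 - (100.0 - level) / 2.0
    ci_lower = np.nanpercentile(samples, lo, axis=0)
    ci_upper = np.nanpercentile(samples, hi, axis=0)
    return BootstrapResult(samples, ci_lower, ci_upper, level, sample_fraction)


def _subset_statistic(statistic, fn, a_inc, s_inc, m, pick):
    """Evaluate a statistic on a frame subset.

    The built-in statistics get count-based fast paths; a custom callable
    receives ``(active_subset, state_subset, n_states)``.
    """
    s = s_inc[pick]
    a = a_inc[pick]
    if fn is not None:
        return fn(a, s, m)
    occ = np.bincount(s, minlength=m)
    active = np.bincount(s[a], minlength=m)
    if statistic == "likelihood_curve":
        with np.errstate(invalid="ignore"):
            return np.where(occ > 0, active / np.maximum(occ, 1), np.nan)
    total = s.shape[0]
    joint_active = active / total
    joint = np.vstack([occ / total - joint_active, joint_active])
    return mutual_info_from_joint(joint)


def bootstrap_ci(raster_row: np.ndarray, stateseq: StateSequence,
                 n_boot: int = 1000, sample_fraction: float = 0.5,
                 level: float = 95.0, seed=None) -> BootstrapResult:
    """Bootstrap percentile CI of the tuning curve P(A|S)."""
    return bootstrap_statistic(raster_row, stateseq, "likelihood_curve",
                               n_boot, sample_fraction, level, seed)
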