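"""Discretization of continuous behavior into behavioral states.

Positions are binned (default 3 cm) into a :class:`~caldecode.core.StateSequence`;
each bin is one discrete state.  Immobility (speed below 5 cm/s by
default) is excluded, since neuronal activity at rest can reflect
internal rather than spatial variables.  For linear tracks the state
space can be direction-augmented, doubling the states into
rightward/leftward copies so that unidirectional place fields are
resolved.
"""

from __future__ import annotations

import numpy as np

from .core import EXCLUDED, BehaviorTrack, StateSequence


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge renormalization."""
    if n <= 1:
        return x.astype(float)
    kern = np.ones(n)
    num = np.convolve(x, kern, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kern, mode="same")
    return num / den


def compute_speed(track: BehaviorTrack, smooth_window_s: float = 0.5) -> np.ndarray:
    """Locomotor speed (cm/s) per frame, boxcar-smoothed.

    Euclidean displacement between consecutive samples divided by the
    time step; the first frame copies the second (no displacement is
    defined for it).
    """
    if track.n_samples < 2:
        raise ValueError("need at least 2 samples to compute speed")
    dt = np.diff(track.timestamps)
    disp = np.linalg.norm(np.diff(track.position, axis=0), axis=1)
    inst = np.empty(track.n_samples)
    inst[1:] = disp / dt
    inst[0] = inst[1]
    n = int(round(smooth_window_s * track.n_samples / max(track.duration_s, 1e-12)))
    return _boxcar(inst, max(n, 1))


def _signed_velocity(track: BehaviorTrack, smooth_window_s: float = 0.5) -> np.ndarray:
    """Smoothed signed 1D velocity (cm/s); positive = rightward."""
    dt = np.diff(track.timestamps)
    inst = np.empty(track.n_samples)
    inst[1:] = np.diff(track.position[:, 0]) / dt
    inst[0] = inst[1]
    n = int(round(smooth_window_s * track.n_samples / max(track.duration_s, 1e-12)))
    return _boxcar(inst, max(n, 1))


def _bin_edges(length: float, bin_width: float, mode: str) -> np.ndarray:
    m = int(np.ceil(length / bin_width))
    if mode == "truncate":
        edges = np.arange(m + 1, dtype=float) * bin_width
        edges[-1] = length  # last bin may be narrower
    elif mode == "equal":
        edges = np.linspace(0.0, length, m + 1)
    else:
        raise ValueError(f"unknown bin mode {mode!r}")
    return edges


def discretize_1d(track: BehaviorTrack, bin_width_cm: float = 3.0,
                  mode: str = "truncate") -> StateSequence:
    """Bin a 1D track into ``ceil(length / bin_width)`` states.

    Bins are half-open ``[k*w, (k+1)*w)``; the far wall clamps into the
    last bin.  In the default ``"truncate"`` mode the last bin is
    narrower when the track length is not a multiple of the bin width
    (e.g. 100 cm / 3 cm -> 34 states, last bin 1 cm); ``"equal"`` mode
    uses M equal-width bins instead.
    """
    if bin_width_cm <= 0:
        raise ValueError("bin_width_cm must be > 0")
    if track.ndim != 1:
        raise ValueError("discretize_1d requires a 1D track")
    lo, hi = track.arena_bounds[0]
    length = hi - lo
    edges = _bin_edges(length, bin_width_cm, mode)
    m = len(edges) - 1
    x = track.position[:, 0] - lo
    if mode == "truncate":
        state = np.floor(x / bin_width_cm).astype(np.int64)
    else:
        state = np.floor(x / (length / m)).astype(np.int64)
    state = np.clip(state, 0, m - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0 + lo
    extents = np.diff(edges)
    return StateSequence(state, m, centers[:, None], extents[:, None])


def discretize_2d(track: BehaviorTrack, bin_cm: float = 3.0,
                  mode: str = "truncate") -> StateSequence:
    """Bin a 2D arena into a row-major ``ny x nx`` grid of states."""
    if bin_cm <= 0:
        raise ValueError("bin_cm must be > 0")
    if track.ndim != 2:
        raise ValueError("discretize_2d requires a 2D track")
    lo = track.arena_bounds[:, 0]
    hi = track.arena_bounds[:, 1]
    ex = _bin_edges(hi[0] - lo[0], bin_cm, mode)
    ey = _bin_edges(hi[1] - lo[1], bin_cm, mode)
    nx, ny = len(ex) - 1, len(ey) - 1
    ix = np.clip(np.searchsorted(ex, track.position[:, 0] - lo[0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(ey, track.position[:, 1] - lo[1], side="right") - 1, 0, ny - 1)
    state = iy * nx + ix
    cx = (ex[:-1] + ex[1:]) / 2.0 + lo[0]
    cy = (ey[:-1] + ey[1:]) / 2.0 + lo[1]
    centers = np.array([(x, y) for y in cy for x in cx])
    extents = np.array([(wx, wy) for wy in np.diff(ey) for wx in np.diff(ex)])
    return StateSequence(state, nx * ny, centers, extents, grid_shape=(ny, nx))


def augment_direction(stateseq: StateSequence, track: BehaviorTrack,
                      min_dir_speed_cms: float = 2.0,
                      smooth_window_s: float = 0.5) -> StateSequence:
    """Split each 1D spatial state into rightward/leftward variants.

    Rightward frames (smoothed velocity > +threshold) keep their state
    id; leftward frames map to ``s + M``; frames slower than the
    direction threshold are excluded rather than guessed.
    """
    if stateseq.ndim != 1 or stateseq.grid_shape is not None:
        raise ValueError("direction augmentation requires a 1D state sequence")
    if track.n_samples != stateseq.n_frames:
        raise ValueError("track and state sequence must share a frame clock")
    vel = _signed_velocity(track, smooth_window_s)
    m = stateseq.n_states
    sid = stateseq.state_id.copy()
    valid = sid != EXCLUDED
    leftward = valid & (vel < -min_dir_speed_cms)
    ambiguous = valid & (np.abs(vel) <= min_dir_speed_cms)
    sid[leftward] += m
    sid[ambiguous] = EXCLUDED
    centers = np.vstack([stateseq.centers, stateseq.centers])
    extents = np.vstack([stateseq.extents, stateseq.extents])
    direction = np.array(["right"] * m + ["left"] * m, dtype=object)
    return StateSequence(sid, 2 * m, centers, extents, direction)


def exclude_immobility(stateseq: StateSequence, speed: np.ndarray,
                       min_speed_cms: float = 5.0) -> StateSequence:
    """Exclude frames below the immobility speed threshold (union with
    any existing exclusions)."""
    speed = np.asarray(speed, dtype=float)
    if speed.shape[0] != stateseq.n_frames:
        raise ValueError("speed must be aligned to frames")
    return stateseq.restrict(speed >= min_speed_cms)
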