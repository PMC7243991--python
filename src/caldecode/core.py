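"""Core data containers shared across the pipeline.

The pipeline operates on three aligned objects sharing one frame clock:
fluorescence traces (:class:`CalciumTraces`), their binarized counterpart
(:class:`BinaryRaster`), and the discretized behavior
(:class:`StateSequence`).  Frames excluded from analysis (immobility,
ambiguous running direction, missing tracking) carry the sentinel state
:data:`EXCLUDED` and are ignored by every probability estimate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Sentinel state id marking frames excluded from all estimates.
EXCLUDED: int = -1


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CalciumTraces:
    """Neuron x frame fluorescence matrix with its frame clock.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, n_frames)
        Fluorescence in arbitrary units; must be finite.
    sampling_rate : float
        Imaging rate in Hz (> 0).
    timestamps : ndarray, shape (n_frames,), optional
        Frame times in seconds.  Built from the sampling rate if omitted.
    """

    values: np.ndarray
    sampling_rate: float
    timestamps: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames) / self.sampling_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape[0] != self.n_frames:
                raise ValueError("timestamp count must equal frame count")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class BehaviorTrack:
    """Tracked position over time in an arena.

    ``position`` is (n_samples, ndim) in cm with ndim 1 (linear track) or
    2 (open field); ``arena_bounds`` is (ndim, 2) rows of [low, high] cm.
    """

    timestamps: np.ndarray
    position: np.ndarray
    arena_bounds: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim == 1:
            self.position = self.position[:, None]
        self.arena_bounds = np.atleast_2d(np.asarray(self.arena_bounds, dtype=float))
        if self.timestamps.ndim != 1 or self.timestamps.shape[0] != self.position.shape[0]:
            raise ValueError("one position record per timestamp required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.arena_bounds.shape != (self.ndim, 2):
            raise ValueError("arena_bounds must be (ndim, 2)")
        lo, hi = self.arena_bounds[:, 0], self.arena_bounds[:, 1]
        if np.any(self.position < lo - 1e-9) or np.any(self.position > hi + 1e-9):
            raise ValueError("positions fall outside arena_bounds")

    @property
    def ndim(self) -> int:
        return self.position.shape[1]

    @property
    def n_samples(self) -> int:
        return self.position.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class BinaryRaster:
    """Neuron x frame active/inactive states produced by a binarization method."""

    states: np.ndarray
    sampling_rate: float
    method: str = "unknown"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        states = np.atleast_2d(np.asarray(self.states))
        if not np.isin(states, (0, 1)).all():
            raise ValueError("raster states must be strictly binary")
        self.states = states.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]


@dataclass
class StateSequence:
    """Per-frame discrete behavioral state with exclusion mask.

    ``state_id`` holds an integer in [0, n_states) per frame or
    :data:`EXCLUDED`.  ``centers``/``extents`` give each state's bin center
    and width in cm (one row per state); ``direction`` optionally labels
    each state ``"left"``/``"right"`` when the sequence is
    direction-augmented; ``grid_shape`` is (ny, nx) for 2D grids so that
    tuning maps can be reshaped and smoothed on the grid.
    """

    state_id: np.ndarray
    n_states: int
    centers: np.ndarray
    extents: np.ndarray
    direction: Optional[np.ndarray] = None
    grid_shape: Optional[tuple] = None

    def __post_init__(self):
        self.state_id = np.asarray(self.state_id, dtype=np.int64)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] != self.n_states:
            raise ValueError("geometry must have exactly n_states entries")
        self.extents = np.atleast_2d(np.asarray(self.extents, dtype=float))
        inc = self.state_id != EXCLUDED
        if inc.any():
            ids = self.state_id[inc]
            if ids.min() < 0 or ids.max() >= self.n_states:
                raise ValueError("state ids out of range")

    @property
    def n_frames(self) -> int:
        return self.state_id.shape[0]

    @property
    def included_mask(self) -> np.ndarray:
        return self.state_id != EXCLUDED

    @property
    def ndim(self) -> int:
        return self.centers.shape[1]

    def restrict(self, mask: np.ndarray) -> "StateSequence":
        """Return a copy with frames outside ``mask`` marked EXCLUDED."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.n_frames:
            raise ValueError("mask length must equal frame count")
        sid = self.state_id.copy()
        sid[~mask] = EXCLUDED
        return StateSequence(sid, self.n_states, self.centers, self.extents,
                             self.direction, self.grid_shape)

    def occupancy(self) -> np.ndarray:
        """Frame counts per state over included frames."""
        inc = self.included_mask
        return np.bincount(self.state_id[inc], minlength=self.n_states)
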