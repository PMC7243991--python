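"""Synthetic place-cell sessions with known ground truth.

Emulates a typical one-photon miniscope experiment: ~15 min sessions at
30 Hz, tens to hundreds of CA1-like neurons with Gaussian place fields on
a 100 cm linear track or a 45 x 45 cm open field, optional
direction-selective cells, inhomogeneous occupancy with immobility bouts
at the track ends, and GCaMP6f-like transients (fast rise, slow decay,
additive Gaussian noise).  Every quantity that downstream estimators try
to recover (field center and width, peak and baseline activity
probability, direction preference) is stored alongside the data, so the
generator doubles as the ground truth for recovery tests.

Behavior is generated directly on the imaging frame clock; aligning a
separately-clocked behavior camera is the job of :mod:`caldecode.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import BehaviorTrack, CalciumTraces, _as_rng


@dataclass
class SyntheticSession:
    """A complete simulated recording: behavior, spikes, traces, truth."""

    track: BehaviorTrack
    spikes: np.ndarray            # neuron x frame event counts
    traces: CalciumTraces
    ground_truth: pd.DataFrame    # one row per neuron
    seed: Optional[int] = None

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.spikes.shape[1]


def simulate_behavior_1d(duration_s: float, sampling_rate_hz: float = 30.0,
                         track_length_cm: float = 100.0,
                         mean_speed_cms: float = 20.0,
                         pause_prob: float = 0.5,
                         mean_pause_s: float = 2.0,
                         speed_jitter: float = 0.2,
                         seed=None) -> BehaviorTrack:
    """Back-and-forth running on a linear track with end-of-track pauses.

    The animal runs ballistically at ``mean_speed_cms`` with multiplicative
    Gaussian speed jitter (SD ``speed_jitter`` x mean), reverses at the
    track ends, and on each arrival pauses with probability ``pause_prob``
    for an exponentially distributed bout (mean ``mean_pause_s``) —
    mimicking reward consumption at the ends of a linear track.
    """
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be > 0")
    if track_length_cm <= 0:
        raise ValueError("track_length_cm must be > 0")
    rng = _as_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    dt = 1.0 / sampling_rate_hz
    pos = np.empty(n)
    x, direction = 0.0, 1.0
    pause_left = 0.0
    for t in range(n):
        pos[t] = x
        if pause_left > 0:
            pause_left -= dt
            continue
        speed = mean_speed_cms * max(0.0, 1.0 + speed_jitter * rng.standard_normal())
        x += direction * speed * dt
        if x >= track_length_cm or x <= 0.0:
            x = min(max(x, 0.0), track_length_cm)
            direction = -direction
            if pause_prob > 0 and rng.random() < pause_prob:
                pause_left = rng.exponential(mean_pause_s)
    ts = np.arange(n) * dt
    return BehaviorTrack(ts, pos, [[0.0, track_length_cm]])


def simulate_behavior_2d(duration_s: float, sampling_rate_hz: float = 30.0,
                         arena_cm=(45.0, 45.0), mean_speed_cms: float = 20.0,
                         heading_sd_rad: float = 0.35,
                         speed_jitter: float = 0.25,
                         seed=None) -> BehaviorTrack:
    """Persistent random walk in a rectangular arena with reflecting walls."""
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be > 0")
    w, h = float(arena_cm[0]), float(arena_cm[1])
    rng = _as_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    dt = 1.0 / sampling_rate_hz
    pos = np.empty((n, 2))
    x, y = w / 2.0, h / 2.0
    heading = rng.uniform(0, 2 * np.pi)
    for t in range(n):
        pos[t] = (x, y)
        heading += heading_sd_rad * rng.standard_normal()
        speed = mean_speed_cms * max(0.0, 1.0 + speed_jitter * rng.standard_normal())
        dx = speed * dt * math.cos(heading)
        dy = speed * dt * math.sin(heading)
        x, y = x + dx, y + dy
        # reflect off walls, flipping the corresponding velocity component
        if x < 0 or x > w:
            x = -x if x < 0 else 2 * w - x
            dx = -dx
        if y < 0 or y > h:
            y = -y if y < 0 else 2 * h - y
            dy = -dy
        if dx != 0 or dy != 0:
            heading = math.atan2(dy, dx)
    ts = np.arange(n) * dt
    return BehaviorTrack(ts, pos, [[0.0, w], [0.0, h]])


def simulate_place_cells(track: BehaviorTrack, n_cells: int,
                         field_width_cm: float = 5.0, p_max: float = 0.3,
                         baseline: float = 0.01,
                         frac_directional: float = 0.0,
                         center_jitter_cm: float = 3.0,
                         seed=None):
    """Draw Bernoulli place-cell events along a trajectory.

    Per frame, a cell emits an event with probability
    ``baseline + (p_max - baseline) * exp(-d^2 / (2 * width^2))`` where
    ``d`` is the distance from the animal to the cell's field center.
    Field centers tile the arena evenly with uniform jitter of
    ``+/- center_jitter_cm``.  A fraction of cells is direction-selective:
    they use the place-field rate only when the animal moves in their
    preferred direction and fire at baseline otherwise (1D tracks only).

    Returns ``(spikes, ground_truth)`` with spikes a neuron x frame count
    matrix and ground_truth a DataFrame of the generating parameters.
    """
    if p_max <= baseline:
        raise ValueError("p_max must exceed baseline")
    if not (0.0 <= p_max <= 1.0 and baseline >= 0.0):
        raise ValueError("p_max and baseline must be probabilities")
    if not 0.0 <= frac_directional <= 1.0:
        raise ValueError("frac_directional must be in [0, 1]")
    rng = _as_rng(seed)
    ndim = track.ndim
    lo = track.arena_bounds[:, 0]
    hi = track.arena_bounds[:, 1]
    n_frames = track.n_samples

    if ndim == 1:
        centers = np.linspace(lo[0], hi[0], n_cells + 2)[1:-1][:, None]
    else:
        side = int(np.ceil(np.sqrt(n_cells)))
        gx = np.linspace(lo[0], hi[0], side + 2)[1:-1]
        gy = np.linspace(lo[1], hi[1], side + 2)[1:-1]
        grid = np.array([(x, y) for y in gy for x in gx])
        centers = grid[:n_cells]
    centers = centers + rng.uniform(-center_jitter_cm, center_jitter_cm, centers.shape)
    centers = np.clip(centers, lo, hi)

    n_dir = int(round(frac_directional * n_cells))
    prefs = np.array(["none"] * n_cells, dtype=object)
    if ndim == 1 and n_dir > 0:
        which = rng.choice(n_cells, size=n_dir, replace=False)
        prefs[which] = np.where(np.arange(n_dir) % 2 == 0, "right", "left")

    d2 = np.sum((track.position[None, :, :] - centers[:, None, :]) ** 2, axis=2)
    rate = baseline + (p_max - baseline) * np.exp(-d2 / (2.0 * field_width_cm ** 2))

    if ndim == 1 and n_dir > 0:
        vel = np.gradient(track.position[:, 0], track.timestamps)
        for k in np.flatnonzero(prefs != "none"):
            moving_pref = vel > 0 if prefs[k] == "right" else vel < 0
            rate[k, ~moving_pref] = baseline

    spikes = (rng.random((n_cells, n_frames)) < rate).astype(np.int64)
    gt = pd.DataFrame({
        "field_width_cm": field_width_cm,
        "p_max": p_max,
        "baseline": baseline,
        "direction_pref": prefs,
    })
    for d in range(ndim):
        gt[f"center_{'xy'[d]}" if ndim == 2 else "center_cm"] = centers[:, d]
    return spikes, gt


def transient_kernel(sampling_rate_hz: float, tau_rise_s: float,
                     tau_decay_s: float, amplitude: float = 1.0) -> np.ndarray:
    """Double-exponential calcium transient a*(exp(-t/tau_d) - exp(-t/tau_r))."""
    if not tau_decay_s > tau_rise_s > 0:
        raise ValueError("require tau_decay > tau_rise > 0")
    t = np.arange(0.0, 10.0 * tau_decay_s, 1.0 / sampling_rate_hz)
    return amplitude * (np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s))


def kernel_peak_time(tau_rise_s: float, tau_decay_s: float) -> float:
    """Closed-form time of the double-exponential kernel maximum."""
    return (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
            * math.log(tau_decay_s / tau_rise_s))


def synthesize_calcium(spikes: np.ndarray, sampling_rate_hz: float = 30.0,
                       tau_rise_s: float = 0.1, tau_decay_s: float = 1.0,
                       amplitude: float = 1.0, noise_sd: float = 0.1,
                       seed=None) -> CalciumTraces:
    """Convolve event counts with a GCaMP6f-like kernel plus Gaussian noise.

    Each event adds the :func:`transient_kernel` from its frame onward;
    synthesis is therefore linear in the events.  Default kinetics
    (tau_rise 0.1 s, tau_decay 1.0 s) are conventional GCaMP6f values.
    """
    spikes = np.atleast_2d(np.asarray(spikes, dtype=float))
    rng = _as_rng(seed)
    kern = transient_kernel(sampling_rate_hz, tau_rise_s, tau_decay_s, amplitude)
    traces = fftconvolve(spikes, kern[None, :], mode="full", axes=1)
    traces = traces[:, :spikes.shape[1]]
    if noise_sd > 0:
        traces = traces + noise_sd * rng.standard_normal(traces.shape)
    return CalciumTraces(traces, sampling_rate_hz)


def make_session_1d(duration_s: float = 900.0, sampling_rate_hz: float = 30.0,
                    track_length_cm: float = 100.0, n_cells: int = 60,
                    mean_speed_cms: float = 20.0, pause_prob: float = 0.5,
                    field_width_cm: float = 5.0, p_max: float = 0.3,
                    baseline: float = 0.01, frac_directional: float = 0.0,
                    tau_rise_s: float = 0.1, tau_decay_s: float = 1.0,
                    amplitude: float = 1.0, noise_sd: float = 0.1,
                    seed: Optional[int] = None) -> SyntheticSession:
    """Standard 15 min linear-track session used throughout the test suite."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_cells, s_ca = ss.spawn(3)
    track = simulate_behavior_1d(duration_s, sampling_rate_hz, track_length_cm,
                                 mean_speed_cms, pause_prob,
                                 seed=np.random.default_rng(s_beh))
    spikes, gt = simulate_place_cells(track, n_cells, field_width_cm, p_max,
                                      baseline, frac_directional,
                                      seed=np.random.default_rng(s_cells))
    traces = synthesize_calcium(spikes, sampling_rate_hz, tau_rise_s,
                                tau_decay_s, amplitude, noise_sd,
                                seed=np.random.default_rng(s_ca))
    return SyntheticSession(track, spikes, traces, gt, seed)


def make_session_2d(duration_s: float = 900.0, sampling_rate_hz: float = 30.0,
                    arena_cm=(45.0, 45.0), n_cells: int = 100,
                    mean_speed_cms: float = 20.0, field_width_cm: float = 5.0,
                    p_max: float = 0.3, baseline: float = 0.01,
                    tau_rise_s: float = 0.1, tau_decay_s: float = 1.0,
                    amplitude: float = 1.0, noise_sd: float = 0.1,
                    seed: Optional[int] = None) -> SyntheticSession:
    """Open-field analogue of :func:`make_session_1d`."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_cells, s_ca = ss.spawn(3)
    track = simulate_behavior_2d(duration_s, sampling_rate_hz, arena_cm,
                                 mean_speed_cms,
                                 seed=np.random.default_rng(s_beh))
    spikes, gt = simulate_place_cells(track, n_cells, field_width_cm, p_max,
                                      baseline, 0.0,
                                      seed=np.random.default_rng(s_cells))
    traces = synthesize_calcium(spikes, sampling_rate_hz, tau_rise_s,
                                tau_decay_s, amplitude, noise_sd,
                                seed=np.random.default_rng(s_ca))
    return SyntheticSession(track, spikes, traces, gt, seed)


def save_session(session: SyntheticSession, path) -> None:
    """Write a session to HDF5 (datasets /traces, /spikes, /behavior/*)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces.values)
        f.create_dataset("spikes", data=session.spikes)
        f.create_dataset("behavior/position", data=session.track.position)
        f.create_dataset("behavior/time", data=session.track.timestamps)
        f.create_dataset("behavior/arena_bounds", data=session.track.arena_bounds)
        f.attrs["sampling_rate"] = session.traces.sampling_rate
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        g = f.create_group("ground_truth")
        for col in session.ground_truth.columns:
            data = session.ground_truth[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)


def load_session(path) -> SyntheticSession:
    """Inverse of :func:`save_session`."""
    import h5py

    with h5py.File(path, "r") as f:
        rate = float(f.attrs["sampling_rate"])
        track = BehaviorTrack(f["behavior/time"][()], f["behavior/position"][()],
                              f["behavior/arena_bounds"][()])
        traces = CalciumTraces(f["traces"][()], rate)
        spikes = f["spikes"][()]
        gt = {}
        for col in f["ground_truth"]:
            data = f["ground_truth"][col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            gt[col] = data
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    return SyntheticSession(track, spikes, traces, pd.DataFrame(gt), seed)
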