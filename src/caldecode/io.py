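"""File I/O, timestamp alignment, configuration, and the full pipeline.

Two dialects are supported throughout: comma-separated text with a
header row, and HDF5.  Traces are neuron x frame; behavior files carry a
``time`` column plus one (``x``) or two (``x``, ``y``) position columns
in cm.  Behavior tracked on its own camera clock is linearly
interpolated onto the imaging frame clock before discretization.

All randomness in a pipeline run flows from one master seed through
``numpy.random.SeedSequence`` spawning; no stage reads global state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import BehaviorTrack, CalciumTraces
from . import binarize as _binarize
from . import decoder as _decoder
from . import states as _states
from . import tuning as _tuning
from . import significance as _significance
from . import encoder as _encoder

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid configuration."""


class AlignmentError(ValueError):
    """Behavior does not cover the imaging frames."""


# ---------------------------------------------------------------- traces

def read_traces(path, sampling_rate: Optional[float] = None) -> CalciumTraces:
    """Read a neuron x frame trace matrix from CSV or HDF5.

    HDF5 files carry the sampling rate as an attribute of the ``traces``
    dataset (or file); for CSV it must be passed explicitly.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["traces"]
            values = ds[()]
            rate = ds.attrs.get("sampling_rate", f.attrs.get("sampling_rate"))
            ts = f["timestamps"][()] if "timestamps" in f else None
        if sampling_rate is not None:
            rate = sampling_rate
        if rate is None:
            raise ConfigError("no sampling_rate attribute and no override given")
        return CalciumTraces(values, float(rate), ts)
    if sampling_rate is None:
        raise ConfigError("sampling_rate is required for delimited-text traces")
    df = pd.read_csv(path, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(f"NaN trace value at row {r}, column {c} in {path}")
    return CalciumTraces(values, float(sampling_rate))


def write_traces(traces: CalciumTraces, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("traces", data=traces.values)
            ds.attrs["sampling_rate"] = traces.sampling_rate
            f.create_dataset("timestamps", data=traces.timestamps)
        return
    cols = [f"frame_{i}" for i in range(traces.n_frames)]
    pd.DataFrame(traces.values, columns=cols).to_csv(path, index=False,
                                                     float_format="%.17g")


# -------------------------------------------------------------- behavior

def read_behavior(path) -> BehaviorTrack:
    """Read a behavior table (columns: time, x[, y]) from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] not in (2, 3):
        raise FormatError("behavior file needs time + 1 or 2 position columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    pos = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError("behavior timestamps must be strictly increasing")
    bounds = np.column_stack([pos.min(axis=0), pos.max(axis=0)])
    return BehaviorTrack(t, pos, bounds)


def write_behavior(track: BehaviorTrack, path) -> None:
    cols = {"time": track.timestamps}
    for d in range(track.ndim):
        cols["xy"[d]] = track.position[:, d]
    pd.DataFrame(cols).to_csv(path, index=False)


def align_behavior_to_frames(track: BehaviorTrack,
                             frame_timestamps: np.ndarray,
                             min_coverage: float = 0.99,
                             ) -> Tuple[BehaviorTrack, np.ndarray]:
    """Interpolate behavior onto the imaging frame clock.

    Returns the resampled track plus a boolean mask of frames inside the
    behavior-coverage interval (frames outside should be excluded).
    Raises :class:`AlignmentError` when behavior covers less than
    ``min_coverage`` of the frame range.
    """
    frame_timestamps = np.asarray(frame_timestamps, dtype=float)
    covered = ((frame_timestamps >= track.timestamps[0])
               & (frame_timestamps <= track.timestamps[-1]))
    coverage = covered.mean()
    if coverage < min_coverage:
        raise AlignmentError(
            f"behavior covers only {coverage:.1%} of imaging frames "
            f"(behavior [{track.timestamps[0]:.2f}, {track.timestamps[-1]:.2f}] s, "
            f"frames [{frame_timestamps[0]:.2f}, {frame_timestamps[-1]:.2f}] s)")
    pos = np.column_stack([
        np.interp(frame_timestamps, track.timestamps, track.position[:, d])
        for d in range(track.ndim)])
    aligned = BehaviorTrack(frame_timestamps, pos, track.arena_bounds)
    return aligned, covered


# ---------------------------------------------------------------- config

@dataclass
class SessionConfig:
    """Validated parameters for one end-to-end pipeline run."""

    traces_path: str = ""
    behavior_path: str = ""
    output_dir: str = "caldecode_out"
    sampling_rate: Optional[float] = None
    seed: int = 0
    binarization: dict = field(default_factory=lambda: {
        "method": "rise", "z_threshold": 2.0, "lowpass_cutoff_hz": 2.0})
    discretization: dict = field(default_factory=lambda: {
        "bin_width_cm": 3.0, "direction": False, "min_speed_cms": 5.0})
    significance: dict = field(default_factory=lambda: {
        "n_shuffles": 1000, "alpha": 0.05, "tie_mode": "strict"})
    bootstrap: dict = field(default_factory=lambda: {
        "n_boot": 1000, "fraction": 0.5, "level": 95.0})
    decoder: dict = field(default_factory=lambda: {
        "prior_mode": "uniform", "variant": "log_product", "window_s": 0.5,
        "train_fraction": 0.5, "block_s": 5.0, "trials": 5})

    def validate(self) -> None:
        b, d, s, bt, dc = (self.binarization, self.discretization,
                           self.significance, self.bootstrap, self.decoder)
        checks = [
            (b["method"] in ("rise", "threshold", "deconvolved"), "binarization.method"),
            (d["bin_width_cm"] > 0, "discretization.bin_width_cm"),
            (d["min_speed_cms"] >= 0, "discretization.min_speed_cms"),
            (s["n_shuffles"] >= 1, "significance.n_shuffles"),
            (0 < s["alpha"] < 1, "significance.alpha"),
            (s["tie_mode"] in ("strict", "inclusive"), "significance.tie_mode"),
            (bt["n_boot"] >= 1, "bootstrap.n_boot"),
            (0 < bt["fraction"] <= 1, "bootstrap.fraction"),
            (0 < bt["level"] < 100, "bootstrap.level"),
            (dc["prior_mode"] in _decoder.PRIOR_MODES, "decoder.prior_mode"),
            (dc["variant"] in _decoder.SCORING_VARIANTS, "decoder.variant"),
            (dc["window_s"] >= 0, "decoder.window_s"),
            (0 < dc["train_fraction"] < 1, "decoder.train_fraction"),
            (dc["block_s"] > 0, "decoder.block_s"),
            (dc["trials"] >= 1, "decoder.trials"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigError(f"invalid value for {name}")

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg


# -------------------------------------------------------------- pipeline

def run_pipeline(config: SessionConfig) -> dict:
    """Execute binarize -> discretize -> tune -> significance -> decode ->
    encode per the configuration; write artifacts and a JSON run report.

    Every random stage is seeded from ``config.seed`` by spawning a
    ``SeedSequence`` child per stage, so two runs with the same config
    are identical.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_sig, seed_boot, seed_split = ss.spawn(3)

    traces = read_traces(config.traces_path, config.sampling_rate)
    track = read_behavior(config.behavior_path)
    track, covered = align_behavior_to_frames(track, traces.timestamps)

    b = config.binarization
    if b["method"] == "rise":
        raster = _binarize.binarize_rise(traces, b["z_threshold"],
                                         b["lowpass_cutoff_hz"])
    elif b["method"] == "threshold":
        raster = _binarize.binarize_threshold(traces, b["z_threshold"])
    else:
        raster = _binarize.binarize_from_deconvolved(traces.values,
                                                     traces.sampling_rate)

    d = config.discretization
    if track.ndim == 1:
        stateseq = _states.discretize_1d(track, d["bin_width_cm"])
        if d.get("direction"):
            stateseq = _states.augment_direction(stateseq, track)
    else:
        stateseq = _states.discretize_2d(track, d["bin_width_cm"])
    speed = _states.compute_speed(track)
    stateseq = _states.exclude_immobility(stateseq, speed, d["min_speed_cms"])
    stateseq = stateseq.restrict(covered)

    models = _tuning.estimate_tuning(raster, stateseq)
    mi = np.array([m.mi_bits for m in models])

    s = config.significance
    sig_rng = np.random.default_rng(seed_sig)
    best = int(np.argmax(mi))
    sig = _significance.tuning_significance(
        raster.states[best], stateseq, s["n_shuffles"], s["alpha"],
        s["tie_mode"], sig_rng)
    bt = config.bootstrap
    boot = _significance.bootstrap_ci(
        raster.states[best], stateseq, bt["n_boot"], bt["fraction"],
        bt["level"], np.random.default_rng(seed_boot))

    dc = config.decoder
    splits = _decoder.split_epochs(
        raster.n_frames, stateseq.included_mask, dc["train_fraction"],
        dc["block_s"], raster.sampling_rate, dc["trials"],
        np.random.default_rng(seed_split))
    agreements, mean_errs, median_errs = [], [], []
    for train_mask, test_mask in splits:
        rep = _decoder.train_test_decode(
            raster, stateseq, train_mask, test_mask, dc["prior_mode"],
            dc["variant"], dc["window_s"])
        agreements.append(rep.agreement)
        mean_errs.append(rep.mean_error_cm)
        median_errs.append(rep.median_error_cm)

    recon = _encoder.reconstruct_activity(stateseq, models)

    curves = pd.DataFrame([m.likelihood for m in models])
    curves.to_csv(out / "tuning_curves.csv", index=False)
    pd.DataFrame({"frame": np.arange(stateseq.n_frames),
                  "state_id": stateseq.state_id,
                  "included": stateseq.included_mask.astype(int)}
                 ).to_csv(out / "state_sequence.csv", index=False)
    report = {
        "parameters": asdict(config),
        "n_neurons": raster.n_neurons,
        "n_frames": raster.n_frames,
        "n_states": stateseq.n_states,
        "n_included_frames": int(stateseq.included_mask.sum()),
        "chance_agreement": 1.0 / stateseq.n_states,
        "mi_bits_mean": float(mi.mean()),
        "mi_bits_max": float(mi.max()),
        "best_neuron": best,
        "best_neuron_significant_bins": int(np.sum(sig.p_value < s["alpha"])),
        "best_neuron_ci_width_mean": float(np.nanmean(boot.ci_upper - boot.ci_lower)),
        "decoding": {
            "agreement_mean": float(np.mean(agreements)),
            "mean_error_cm": float(np.mean(mean_errs)),
            "median_error_cm": float(np.mean(median_errs)),
            "n_trials": dc["trials"],
        },
        "encoding_mean_predicted_prob": float(np.nanmean(recon.predicted_prob)),
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    return report
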