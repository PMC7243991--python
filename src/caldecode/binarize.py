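"""Binarization of fluorescence traces into active/inactive epochs.

The primary method marks transient *rise* periods: a frame is active when
the low-pass filtered, z-scored trace exceeds a threshold (default 2 SD)
AND its first derivative is positive.  Because most action potentials
occur during the rising phase of a calcium transient, restricting
activity to rise periods gives a tighter temporal estimate of spiking
than thresholding alone.  Two comparison methods are provided: a plain
z-score threshold, and thresholding of an externally deconvolved matrix
(deconvolution itself, e.g. OASIS, is out of scope — only its output is
consumed).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import BinaryRaster, CalciumTraces

logger = logging.getLogger(__name__)


def _zscore_rows(values: np.ndarray):
    """Row-wise z-score; zero-variance rows yield NaN rows plus a warning."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    dead = sd[:, 0] == 0
    if dead.any():
        logger.warning("%d zero-variance trace(s); marked all-inactive", dead.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[dead] = np.nan
    return z, dead


def lowpass_filter(values: np.ndarray, sampling_rate: float,
                   cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass along axis 1."""
    if not 0 < cutoff_hz < sampling_rate / 2:
        raise ValueError("cutoff must lie in (0, sampling_rate/2)")
    sos = butter(order, cutoff_hz, btype="low", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, values, axis=1)


def binarize_rise(traces: CalciumTraces, z_threshold: float = 2.0,
                  lowpass_cutoff_hz: float = 2.0) -> BinaryRaster:
    """Mark transient rise periods: z > threshold and positive derivative.

    Per neuron the trace is low-pass filtered (zero-phase, order-4
    Butterworth, default 2 Hz cutoff to remove frame noise without
    delaying the rise), z-scored over the whole recording, and frame t is
    active iff ``z(t) > z_threshold`` and ``z(t) - z(t-1) > 0``.  Frame 0
    is inactive (derivative undefined).  Dead (zero-variance) traces are
    all-inactive with a logged warning rather than an error, so dead ROIs
    do not abort batch runs.
    """
    filt = lowpass_filter(traces.values, traces.sampling_rate, lowpass_cutoff_hz)
    z, dead = _zscore_rows(filt)
    rising = np.zeros_like(z, dtype=bool)
    rising[:, 1:] = np.diff(z, axis=1) > 0
    with np.errstate(invalid="ignore"):
        active = (z > z_threshold) & rising
    active[dead] = False
    return BinaryRaster(active, traces.sampling_rate, method="rise",
                        parameters={"z_threshold": z_threshold,
                                    "lowpass_cutoff_hz": lowpass_cutoff_hz})


def binarize_threshold(traces: CalciumTraces, z_threshold: float = 2.0) -> BinaryRaster:
    """Simple z-score threshold on the unfiltered trace."""
    z, dead = _zscore_rows(traces.values)
    with np.errstate(invalid="ignore"):
        active = z > z_threshold
    active[dead] = False
    return BinaryRaster(active, traces.sampling_rate, method="threshold",
                        parameters={"z_threshold": z_threshold})


def binarize_from_deconvolved(deconvolved: np.ndarray,
                              sampling_rate: float = np.nan) -> BinaryRaster:
    """Active wherever a (non-negative) deconvolved matrix is above zero."""
    deconvolved = np.atleast_2d(np.asarray(deconvolved, dtype=float))
    if np.any(deconvolved < 0):
        raise ValueError("deconvolved matrix must be non-negative")
    return BinaryRaster(deconvolved > 0, sampling_rate, method="deconvolved",
                        parameters={})
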