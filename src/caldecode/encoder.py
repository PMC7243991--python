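"""Predicting neuronal activity from behavior (encoding).

The tuning curve P(A|S) is both a measurement and a prediction: given
the animal's state at frame t, each neuron's expected activity
probability is simply its likelihood at that state.  Refining the state
definition (e.g. splitting location into location x running direction)
can sharpen these predictions for direction-selective cells — their peak
likelihood rises once leftward and rightward traversals are no longer
pooled.  Bootstrap mutual information compares how informative competing
state definitions are about a neuron's activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BinaryRaster, StateSequence
from .significance import BootstrapResult, bootstrap_statistic
from .tuning import TuningModel, estimate_tuning


@dataclass
class EncodingReconstruction:
    """Per-frame predicted activity probability per neuron."""

    predicted_prob: np.ndarray   # (N, T); NaN on excluded frames
    thresholded: np.ndarray      # (N, T) binary display raster
    threshold: float


def reconstruct_activity(stateseq: StateSequence,
                         tuning_models: Sequence[TuningModel],
                         threshold: float = 0.5) -> EncodingReconstruction:
    """Look up each neuron's likelihood at the animal's current state.

    Excluded frames (and states undefined in the tuning fit) are NaN.
    The thresholded raster (default 0.5) is for display only; the
    probability matrix is the primary output.
    """
    m = stateseq.n_states
    for tm in tuning_models:
        if tm.n_states != m:
            raise ValueError("tuning state space does not match the sequence")
    inc = stateseq.included_mask
    t = stateseq.n_frames
    pred = np.full((len(tuning_models), t), np.nan)
    s = stateseq.state_id[inc]
    for k, tm in enumerate(tuning_models):
        pred[k, inc] = tm.likelihood[s]
    with np.errstate(invalid="ignore"):
        thresholded = (pred > threshold).astype(np.uint8)
    return EncodingReconstruction(pred, thresholded, threshold)


def compare_state_refinements(raster: BinaryRaster,
                              stateseq_base: StateSequence,
                              stateseq_refined: StateSequence) -> pd.DataFrame:
    """Fit tuning under two state definitions and compare per neuron.

    Typical use: base = location bins, refined = location x direction.
    Reports peak likelihood and MI under each definition.
    """
    if stateseq_base.n_frames != stateseq_refined.n_frames:
        raise ValueError("state sequences must share a frame clock")
    base = estimate_tuning(raster, stateseq_base)
    refined = estimate_tuning(raster, stateseq_refined)
    return pd.DataFrame({
        "peak_likelihood_base": [np.nanmax(tm.likelihood) for tm in base],
        "peak_likelihood_refined": [np.nanmax(tm.likelihood) for tm in refined],
        "mi_base": [tm.mi_bits for tm in base],
        "mi_refined": [tm.mi_bits for tm in refined],
    })


def bootstrap_mi(raster_row: np.ndarray, stateseq: StateSequence,
                 n_boot: int = 1000, sample_fraction: float = 0.5,
                 level: float = 95.0, seed=None) -> BootstrapResult:
    """Bootstrap distribution and percentile CI of mutual information."""
    return bootstrap_statistic(raster_row, stateseq, "mi", n_boot,
                               sample_fraction, level, seed)
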