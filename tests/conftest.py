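"""Shared synthetic-session fixtures.

Sessions are generated once per test run (session scope) because several
test modules exercise the same standard recording conditions: a 15 min
linear-track session at 30 Hz with 60 tiled place cells.
"""

import numpy as np
import pytest

import caldecode as cd
from caldecode.core import StateSequence


@pytest.fixture(scope="session")
def session_1d():
    """Standard linear-track session: 900 s @ 30 Hz, 60 place cells."""
    return cd.make_session_1d(seed=42)


@pytest.fixture(scope="session")
def stateseq_1d(session_1d):
    """3 cm bins with immobility (< 5 cm/s) excluded."""
    seq = cd.discretize_1d(session_1d.track, 3.0)
    speed = cd.compute_speed(session_1d.track)
    return cd.exclude_immobility(seq, speed, 5.0)


@pytest.fixture(scope="session")
def raster_rise_1d(session_1d):
    return cd.binarize_rise(session_1d.traces)


@pytest.fixture(scope="session")
def raster_spikes_1d(session_1d):
    """Ground-truth event raster (bypasses calcium synthesis/binarization)."""
    return cd.binarize_from_deconvolved(session_1d.spikes, 30.0)


@pytest.fixture(scope="session")
def session_2d():
    """Short open-field session for 2D map tests."""
    return cd.make_session_2d(duration_s=300.0, n_cells=16, seed=3)


@pytest.fixture(scope="session")
def stateseq_2d(session_2d):
    seq = cd.discretize_2d(session_2d.track, 3.0)
    speed = cd.compute_speed(session_2d.track)
    return cd.exclude_immobility(seq, speed, 5.0)


def make_stateseq(state_id, n_states, spacing_cm=1.0):
    """Minimal 1D state sequence for hand-constructed examples."""
    centers = (np.arange(n_states, dtype=float) + 0.5)[:, None] * spacing_cm
    extents = np.full((n_states, 1), spacing_cm)
    return StateSequence(np.asarray(state_id), n_states, centers, extents)
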