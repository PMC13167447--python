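"""Shared fixtures: calibrated configs and (cached) simulated slice batches."""

from __future__ import annotations

import numpy as np
import pytest

import slicewave as sw
from slicewave.synthetic import StimulusProtocol


@pytest.fixture(scope="session")
def paper_config():
    """Reference preset at full field size (calibration is cached)."""
    return sw.make_config("paper_table_s1")


@pytest.fixture(scope="session")
def desk_config():
    """Reference preset on the reduced field used for simulation tests."""
    return sw.make_config("paper_table_s1", desk_scale=True)


@pytest.fixture(scope="session")
def paired_protocol():
    return StimulusProtocol.paired_pulse()


@pytest.fixture(scope="session")
def paper_truth(desk_config, paired_protocol):
    return sw.ground_truth(desk_config, paired_protocol)


@pytest.fixture(scope="session")
def twelve_slices(desk_config):
    """Twelve paired-pulse slice experiments through the full pipeline.

    This is the batch used for parameter-recovery and ordering checks; it is
    simulated once per test session.
    """
    return [sw.simulate_and_quantify(desk_config, seed=s) for s in range(1, 13)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_trace(values, frame_rate=5000.0, channel="ca", pulse_times=(), name="t"):
    """Build a bare RoiTrace on the standard time base for unit tests."""
    from slicewave.io import RoiSpec
    from slicewave.roi_signal import RoiTrace

    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) / frame_rate * 1000.0
    return RoiTrace(
        values=values,
        times=times,
        roi=RoiSpec(name, (0, 0), 1),
        channel=channel,
        pulse_times=tuple(pulse_times),
    )
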