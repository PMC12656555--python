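import dataclasses

import numpy as np
import pytest

from flocyt import SimConfig, TrackerConfig
from flocyt.cli_io import benchmark_tracker_config


@pytest.fixture
def small_sim_config():
    """Preset-K physics at reduced length for fast end-to-end tests."""
    return SimConfig.from_preset("K", seed=11, n_frames=120)


@pytest.fixture
def tracker_config(small_sim_config):
    return benchmark_tracker_config(small_sim_config)


def two_lane_detections(n_frames=50, v=(120.0, 100.0), lateral_gap=120.0, x0=(0.0, 30.0)):
    """Two cells in parallel lanes, constant velocities, noiseless."""
    frames = []
    for t in range(n_frames):
        frames.append(
            np.array(
                [
                    [x0[0] + v[0] * t, 300.0],
                    [x0[1] + v[1] * t, 300.0 + lateral_gap],
                ]
            )
        )
    return frames


@pytest.fixture
def roi_full():
    return (0.0, 0.0, 1920.0, 1080.0)
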