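import numpy as np
import pandas as pd
import pytest

from granulekit.synthetic import AcquisitionSpec, disc_masks
from granulekit.tracks import TrackSet


@pytest.fixture
def small_acq():
    """A small noise-free acquisition for fast rendering tests."""
    return AcquisitionSpec(nx=48, ny=48, n_frames=5, noise="none")


@pytest.fixture
def cell_and_centrosome_masks():
    return disc_masks((64, 64), (32, 32), 25, (20, 20), 4)


def make_trackset(coords, frame_interval=0.1):
    """Build a TrackSet from {track_id: (x_array, y_array)} dicts."""
    rows = []
    for tid, (x, y) in coords.items():
        x, y = np.asarray(x, float), np.asarray(y, float)
        rows.append(pd.DataFrame({
            "track_id": tid, "frame": np.arange(len(x)),
            "x_um": x, "y_um": y,
        }))
    return TrackSet(pd.concat(rows, ignore_index=True), frame_interval)


@pytest.fixture
def straight_track():
    """A 3 µm monotone run along x at 0.1 µm/frame."""
    ts = make_trackset({0: (1.0 + 0.1 * np.arange(31), np.zeros(31))})
    return ts.get(0)
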