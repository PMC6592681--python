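import numpy as np
import pytest

from epistrat import SimulationConfig
from epistrat.division import NucleusTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fast_config():
    """A small, quick-to-generate field configuration."""
    return SimulationConfig(field_width=100.0, field_height=100.0, seed=7)


def make_track(cell_id, frames, z, xy=(0.0, 0.0), mother_id=None, frame_interval=10.0):
    """A straight-line track at fixed xy with the given z series."""
    frames = np.asarray(frames)
    z = np.broadcast_to(np.asarray(z, dtype=float), frames.shape)
    pos = np.column_stack([np.full(len(frames), xy[0]), np.full(len(frames), xy[1]), z])
    return NucleusTrack(cell_id=cell_id, frames=frames, positions=pos,
                        mother_id=mother_id, frame_interval=frame_interval)


@pytest.fixture
def track_factory():
    return make_track
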