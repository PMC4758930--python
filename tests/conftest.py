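import numpy as np
import pytest

from lvforce.core import AcquisitionMeta, Landmarks, MaskSeries, VelocityField


@pytest.fixture
def small_meta():
    return AcquisitionMeta(venc=1.0, voxel_size=(3.0, 3.0, 3.0), n_frames=8, rr_interval=800.0)


@pytest.fixture
def small_field(small_meta):
    """8-frame 6x6x6 field with a smooth low-amplitude oscillation."""
    rng = np.random.default_rng(42)
    t = np.arange(small_meta.n_frames)
    base = 0.2 * np.sin(2 * np.pi * t / small_meta.n_frames)
    values = np.zeros((small_meta.n_frames, 3, 6, 6, 6))
    values[:, 0] = base[:, None, None, None]
    values += 0.01 * rng.standard_normal(values.shape)
    return VelocityField(values, small_meta)


@pytest.fixture
def ball_mask(small_meta):
    ax = np.arange(6) - 2.5
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = X**2 + Y**2 + Z**2 <= 2.6**2
    occ = np.broadcast_to(ball, (small_meta.n_frames, 6, 6, 6)).copy()
    return MaskSeries(occ, small_meta.voxel_size)


@pytest.fixture
def simple_landmarks():
    return Landmarks(apex=(30.0, 30.0, 80.0), mv_center=(30.0, 30.0, 0.0), aov_center=(50.0, 30.0, 5.0))
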