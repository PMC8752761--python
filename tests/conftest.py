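import numpy as np
import pytest

from neurovasc3d import (
    BinaryVolume,
    IntensityVolume,
    SceneConfig,
    SegmentationParams,
    Tube,
    VoxelGeometry,
    line_curve,
)
from neurovasc3d.phantoms import rasterise_tube_mask

# analysis parameters calibrated for the synthetic acquisition conditions
# (threshold ≈ background + 4 effective-noise SD after 1 µm denoising)
PHANTOM_SEG = SegmentationParams(threshold_factor=2.0, smoothing_sigma_um=1.0)


def iso_geometry(shape, spacing=1.0):
    return VoxelGeometry((spacing,) * 3, shape)


def volume_from(values, spacing=(1.0, 1.0, 1.0), channel="endothelium"):
    values = np.asarray(values)
    return IntensityVolume(values, VoxelGeometry(spacing, values.shape), channel=channel)


@pytest.fixture(scope="session")
def straight_tube_scene():
    """Noise-free straight tube (radius 3 µm) and its analytic mask."""
    cfg = SceneConfig(shape_zyx=(32, 64, 120),
                      tubes=[Tube(line_curve((16, 32, 5), (16, 32, 115)), 3.0)],
                      noise_sigma=0.0, blur_sigma_um=0.0)
    mask = rasterise_tube_mask(cfg)
    return cfg, BinaryVolume(mask, cfg.geometry)
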