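import numpy as np
import pytest

from spotchip import (
    CalibratedImage2D,
    CalibratedStack3D,
    SyntheticSceneSpec3D,
    SyntheticWellSpec,
    generate_scene,
    generate_well,
)


@pytest.fixture
def flat_image():
    """Constant 64x64 well image at 1 µm/px."""
    return CalibratedImage2D(np.full((64, 64), 100.0), pixel_size_um=1.0, well_id="flat")


@pytest.fixture
def disk_image():
    """Single dark disk (value 0, radius 6 px) on a 255 background, 64x64."""
    arr = np.full((64, 64), 255.0)
    yy, xx = np.mgrid[:64, :64]
    arr[(yy - 32) ** 2 + (xx - 32) ** 2 <= 6**2] = 0.0
    return CalibratedImage2D(arr, pixel_size_um=1.0, well_id="disk")


@pytest.fixture(scope="session")
def clean_well():
    """Noise/blur-free well at 1 µm/px where measured areas equal planted areas.

    Small artifacts ~3 µm diameter and large artifacts >6000 µm² bracket the
    default [40, 4000] µm² filter with wide margins.
    """
    spec = SyntheticWellSpec(
        image_size_px=(512, 512),
        pixel_size_um=1.0,
        n_spots=12,
        spot_diameter_range_um=(15.0, 50.0),
        n_artifacts_small=4,
        n_artifacts_large=2,
        noise_sd=0.0,
        blur_sigma_um=0.0,
        background_gradient=0.0,
        seed=11,
    )
    return spec, *generate_well(spec)


@pytest.fixture(scope="session")
def sphere_scene():
    """Sphere organoid R = 60 µm in (2, 1, 1) µm voxels with three planted
    cells at radii {30, 60-ish, 75} µm (signed distances -30, ~0, +15)."""
    spec = SyntheticSceneSpec3D(
        stack_size_vox=(90, 180, 180),
        voxel_size_um=(2.0, 1.0, 1.0),
        organoid_semi_axes_um=(60.0, 60.0, 60.0),
        cells_inside=[-30.0],
        cells_outside=[15.0],
        seed=7,
    )
    return spec, *generate_scene(spec)
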