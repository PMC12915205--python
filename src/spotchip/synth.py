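"""Seeded synthetic ELISPOT wells and 3D co-culture scenes with ground truth.

Both generators emulate the toolkit's two input classes with exactly known
answers, so they serve as the oracle for end-to-end recovery tests:

* ``generate_well`` renders dark anti-aliased spots (and deliberately
  out-of-range artifacts) on a light membrane with an illumination
  gradient, Gaussian blur, and additive Gaussian noise;
* ``generate_scene`` renders an analytic organoid body (sphere or
  ellipsoid) and anisotropic Gaussian T-cell blobs planted at positions
  whose signed distance to the body surface is known exactly.

A single RNG stream is derived from the seed per call, so identical seeds
give bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import ndimage

from .core import (
    CalibratedImage2D,
    CalibratedStack3D,
    Polarity,
    SizeFilterRange,
    validate_calibration,
)

__all__ = [
    "SyntheticWellSpec",
    "GroundTruth2D",
    "PlantedObject2D",
    "SyntheticSceneSpec3D",
    "GroundTruth3D",
    "PlantedCell3D",
    "generate_well",
    "generate_scene",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PlacementError(RuntimeError):
    """Rejection sampling could not place all requested objects."""


# ---------------------------------------------------------------------------
# 2D wells


class SyntheticWellSpec(BaseModel):
    """Conditions for one synthetic ELISPOT well.

    Defaults emulate a plate-imager field: 768x768 px at 3 µm/px (a 2.3 mm
    crop of a membrane), spots of 15-50 µm diameter darker than the
    background by 60 units, noise SD 10 (signal-to-noise 6), and a mild
    illumination gradient.  Artifact diameters are drawn strictly outside
    ``size_filter`` so planted classes and filter classes coincide.
    """

    image_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 3.0
    n_spots: int = 50
    spot_diameter_range_um: tuple[float, float] = (15.0, 50.0)
    n_artifacts_small: int = 0
    n_artifacts_large: int = 0
    spot_depth: float = 60.0
    background_level: float = 200.0
    background_gradient: float = 0.02
    noise_sd: float = 10.0
    blur_sigma_um: float = 2.0
    min_separation_um: float = 60.0
    size_filter: SizeFilterRange = SizeFilterRange()
    small_artifact_diameter_range_um: tuple[float, float] = (2.0, 3.5)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticWellSpec":
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.spot_diameter_range_um
        if not 0 < lo <= hi:
            raise ValueError("spot_diameter_range_um must be positive and ordered")
        spot_areas = (np.pi / 4.0) * np.array([lo, hi]) ** 2
        sf = self.size_filter
        if spot_areas[0] < sf.min_area_um2 or spot_areas[1] > sf.max_area_um2:
            raise ValueError(
                "planted spot areas must lie inside size_filter: "
                f"{spot_areas} vs [{sf.min_area_um2}, {sf.max_area_um2}]"
            )
        s_lo, s_hi = self.small_artifact_diameter_range_um
        if (np.pi / 4.0) * s_hi**2 >= sf.min_area_um2:
            raise ValueError("small artifacts must be strictly below min_area_um2")
        return self

    def large_artifact_diameter_range_um(self) -> tuple[float, float]:
        """Diameters whose disk area is 1.5-3x the filter's max area."""
        d = 2.0 * np.sqrt(np.array([1.5, 3.0]) * self.size_filter.max_area_um2 / np.pi)
        return (float(d[0]), float(d[1]))


@dataclass
class PlantedObject2D:
    center_um: tuple[float, float]  # (y, x)
    diameter_um: float
    obj_class: str  # spot | artifact_small | artifact_large


@dataclass
class GroundTruth2D:
    objects: list[PlantedObject2D]
    n_spots: int
    n_artifacts_small: int
    n_artifacts_large: int

    def validate(self) -> "GroundTruth2D":
        by_class = {"spot": 0, "artifact_small": 0, "artifact_large": 0}
        for o in self.objects:
            by_class[o.obj_class] += 1
        if (by_class["spot"], by_class["artifact_small"], by_class["artifact_large"]) != (
            self.n_spots,
            self.n_artifacts_small,
            self.n_artifacts_large,
        ):
            raise ValueError("ground-truth totals do not match object list")
        return self

    def to_dict(self) -> dict:
        return {
            "objects": [asdict(o) for o in self.objects],
            "n_spots": self.n_spots,
            "n_artifacts_small": self.n_artifacts_small,
            "n_artifacts_large": self.n_artifacts_large,
        }


def _place_centers(
    rng: np.random.Generator,
    bounds_um: tuple[float, float],
    radii_um: np.ndarray,
    margin_um: np.ndarray,
    min_sep_um: float,
    clearance_um: float,
    max_retries: int = 10_000,
) -> list[np.ndarray]:
    """Rejection-sample centers with radius-aware pairwise separation.

    Two objects must be at least ``max(min_sep, r_i + r_j + clearance)``
    apart so that distinct objects never merge, whatever their sizes.
    """
    placed: list[np.ndarray] = []
    h, w = bounds_um
    n = len(radii_um)
    for i in range(n):
        m = float(margin_um[i])
        for _ in range(max_retries):
            c = rng.uniform([m, m], [h - m, w - m])
            ok = True
            for j, p in enumerate(placed):
                need = max(min_sep_um, radii_um[i] + radii_um[j] + clearance_um)
                if np.linalg.norm(c - p) < need:
                    ok = False
                    break
            if ok:
                placed.append(c)
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{n} after {max_retries} tries; "
                "reduce object count or separation"
            )
    return placed


def _render_disk(img: np.ndarray, center_px: np.ndarray, radius_px: float, depth: float) -> None:
    """Subtract an anti-aliased disk; coverage = clip(R - d + 0.5, 0, 1)."""
    cy, cx = center_px
    r_int = int(np.ceil(radius_px + 1.5))
    y0, y1 = max(0, int(cy) - r_int), min(img.shape[0], int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(img.shape[1], int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    coverage = np.clip(radius_px - d + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] -= depth * coverage


def generate_well(spec: SyntheticWellSpec) -> tuple[CalibratedImage2D, GroundTruth2D]:
    """Render one synthetic well and its exact answer key."""
    rng = np.random.default_rng(spec.seed)
    h_px, w_px = spec.image_size_px
    px = spec.pixel_size_um
    bounds_um = (h_px * px, w_px * px)

    # background plane + linear gradient along x
    xx = np.arange(w_px, dtype=np.float64)[None, :]
    img = np.full((h_px, w_px), spec.background_level, dtype=np.float64)
    img += spec.background_gradient * (xx - w_px / 2.0)

    # draw diameters first so margins are known, then place all objects in
    # one pass (spots, then small, then large artifacts)
    d_spots = rng.uniform(*spec.spot_diameter_range_um, size=spec.n_spots)
    d_small = rng.uniform(
        *spec.small_artifact_diameter_range_um, size=spec.n_artifacts_small
    )
    d_large = rng.uniform(
        *spec.large_artifact_diameter_range_um(), size=spec.n_artifacts_large
    )
    diameters = np.concatenate([d_spots, d_small, d_large])
    classes = (
        ["spot"] * spec.n_spots
        + ["artifact_small"] * spec.n_artifacts_small
        + ["artifact_large"] * spec.n_artifacts_large
    )
    margins = diameters / 2.0 + spec.blur_sigma_um * 3.0 + 2.0 * px
    centers = _place_centers(
        rng,
        bounds_um,
        radii_um=diameters / 2.0,
        margin_um=margins,
        min_sep_um=spec.min_separation_um,
        clearance_um=6.0 * spec.blur_sigma_um + 3.0 * px,
    )

    objects = []
    for c_um, diam, cls in zip(centers, diameters, classes):
        _render_disk(img, c_um / px, (diam / 2.0) / px, spec.spot_depth)
        objects.append(PlantedObject2D((float(c_um[0]), float(c_um[1])), float(diam), cls))

    if spec.blur_sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma_um / px, mode="reflect")
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    image = validate_calibration(
        CalibratedImage2D(
            intensities=img,
            pixel_size_um=px,
            polarity=Polarity.DARK_SPOTS_ON_LIGHT,
            well_id=f"synthetic-{spec.seed}",
        )
    )
    truth = GroundTruth2D(
        objects=objects,
        n_spots=spec.n_spots,
        n_artifacts_small=spec.n_artifacts_small,
        n_artifacts_large=spec.n_artifacts_large,
    ).validate()
    return image, truth


# ---------------------------------------------------------------------------
# 3D scenes


class SyntheticSceneSpec3D(BaseModel):
    """Conditions for one synthetic co-culture chamber stack.

    Defaults emulate a 10x spinning-disk acquisition: (4, 2, 2) µm voxels
    (anisotropic in z), a 100 µm-radius spherical organoid, and T-cell
    blobs of FWHM (10, 5, 5) µm matching the expected cell extents.
    ``cells_inside`` lists requested depths as negative µm; ``cells_outside``
    lists positive clearances.  Cell positions are solved along random
    radial/normal directions so each planted signed distance is exact.
    """

    stack_size_vox: tuple[int, int, int] = (80, 160, 160)
    voxel_size_um: tuple[float, float, float] = (4.0, 2.0, 2.0)
    organoid_shape: str = "sphere"  # sphere | ellipsoid
    organoid_center_um: tuple[float, float, float] | None = None
    organoid_semi_axes_um: tuple[float, float, float] = (100.0, 100.0, 100.0)
    cells_inside: list[float] = []
    cells_outside: list[float] = []
    cell_fwhm_um: tuple[float, float, float] = (10.0, 5.0, 5.0)
    cell_amplitude: float = 120.0
    organoid_intensity: float = 100.0
    background_level: float = 10.0
    noise_sd_tcell: float = 8.0
    noise_sd_organoid: float = 5.0
    min_cell_separation_um: float = 12.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSceneSpec3D":
        if self.organoid_shape not in ("sphere", "ellipsoid"):
            raise ValueError("organoid_shape must be 'sphere' or 'ellipsoid'")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if any(d >= 0 for d in self.cells_inside):
            raise ValueError("cells_inside must be negative depths (µm)")
        if any(d <= 0 for d in self.cells_outside):
            raise ValueError("cells_outside must be positive distances (µm)")
        axes = np.asarray(self.organoid_semi_axes_um)
        if self.organoid_shape == "sphere" and not np.allclose(axes, axes[0]):
            raise ValueError("sphere requires equal semi-axes")
        # normal offsets are exact only up to the minimal curvature radius
        # (c^2/a for an ellipsoid; R for a sphere)
        max_depth = float(axes.min() ** 2 / axes.max())
        for d in self.cells_inside:
            if -d >= max_depth:
                raise ValueError(
                    f"requested depth {d} µm exceeds the exact-placement limit "
                    f"(-{max_depth:.1f} µm) of this body"
                )
        return self

    def center_um(self) -> np.ndarray:
        if self.organoid_center_um is not None:
            return np.asarray(self.organoid_center_um, dtype=float)
        shape = np.asarray(self.stack_size_vox, dtype=float)
        voxel = np.asarray(self.voxel_size_um, dtype=float)
        return (shape - 1.0) * voxel / 2.0

    def analytic_volume_um3(self) -> float:
        az, ay, ax = self.organoid_semi_axes_um
        return float(4.0 / 3.0 * np.pi * az * ay * ax)


@dataclass
class PlantedCell3D:
    position_um: tuple[float, float, float]  # (z, y, x)
    signed_distance_um: float
    label: str  # inside | outside


@dataclass
class GroundTruth3D:
    cells: list[PlantedCell3D]
    organoid_center_um: tuple[float, float, float]
    organoid_semi_axes_um: tuple[float, float, float]
    organoid_shape: str
    analytic_volume_um3: float

    @property
    def n_inside(self) -> int:
        return sum(1 for c in self.cells if c.label == "inside")

    @property
    def n_outside(self) -> int:
        return sum(1 for c in self.cells if c.label == "outside")

    def to_dict(self) -> dict:
        return {
            "cells": [asdict(c) for c in self.cells],
            "organoid_center_um": list(self.organoid_center_um),
            "organoid_semi_axes_um": list(self.organoid_semi_axes_um),
            "organoid_shape": self.organoid_shape,
            "analytic_volume_um3": self.analytic_volume_um3,
        }


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _ellipsoid_point_and_normal(
    rng: np.random.Generator, axes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """A random surface point of the axis-aligned ellipsoid and its outward normal."""
    u = _random_unit_vector(rng)
    p = axes * u  # maps the unit sphere onto the ellipsoid surface
    n = p / axes**2
    return p, n / np.linalg.norm(n)


def _solve_cell_position(
    rng: np.random.Generator,
    spec: SyntheticSceneSpec3D,
    signed_d: float,
) -> np.ndarray:
    """Position (relative to center) whose signed surface distance is signed_d."""
    axes = np.asarray(spec.organoid_semi_axes_um, dtype=float)
    if spec.organoid_shape == "sphere":
        r = axes[0] + signed_d  # signed_d < 0 inside
        return r * _random_unit_vector(rng)
    p, n = _ellipsoid_point_and_normal(rng, axes)
    return p + signed_d * n


def generate_scene(
    spec: SyntheticSceneSpec3D,
) -> tuple[CalibratedStack3D, GroundTruth3D]:
    """Render one synthetic chamber stack and its exact answer key."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.stack_size_vox)
    voxel = np.asarray(spec.voxel_size_um, dtype=float)
    center = spec.center_um()
    axes = np.asarray(spec.organoid_semi_axes_um, dtype=float)
    extent = (np.asarray(shape) - 1) * voxel

    # solve cell positions; re-draw directions that leave the stack or crowd
    requested = [(d, "inside") for d in spec.cells_inside] + [
        (d, "outside") for d in spec.cells_outside
    ]
    margin = np.asarray(spec.cell_fwhm_um, dtype=float)
    placed: list[np.ndarray] = []
    cells: list[PlantedCell3D] = []
    for signed_d, label in requested:
        for _ in range(10_000):
            pos = center + _solve_cell_position(rng, spec, signed_d)
            if np.any(pos < margin) or np.any(pos > extent - margin):
                continue
            if all(
                np.linalg.norm(pos - q) >= spec.min_cell_separation_um for q in placed
            ):
                placed.append(pos)
                cells.append(
                    PlantedCell3D(tuple(float(v) for v in pos), float(signed_d), label)
                )
                break
        else:
            raise PlacementError(
                f"could not place a cell at signed distance {signed_d} µm; "
                "enlarge the stack or relax separation"
            )

    # physical voxel-center coordinate grids
    zc = np.arange(shape[0], dtype=np.float64)[:, None, None] * voxel[0]
    yc = np.arange(shape[1], dtype=np.float64)[None, :, None] * voxel[1]
    xc = np.arange(shape[2], dtype=np.float64)[None, None, :] * voxel[2]

    organoid = np.full(shape, spec.background_level, dtype=np.float64)
    inside = (
        ((zc - center[0]) / axes[0]) ** 2
        + ((yc - center[1]) / axes[1]) ** 2
        + ((xc - center[2]) / axes[2]) ** 2
    ) <= 1.0
    organoid[inside] += spec.organoid_intensity

    tcell = np.full(shape, spec.background_level, dtype=np.float64)
    sigma = np.asarray(spec.cell_fwhm_um, dtype=float) * FWHM_TO_SIGMA
    for cell in cells:
        pos = np.asarray(cell.position_um)
        # render within a +/- 4 sigma window for speed
        lo = np.maximum(np.floor((pos - 4 * sigma) / voxel).astype(int), 0)
        hi = np.minimum(np.ceil((pos + 4 * sigma) / voxel).astype(int) + 1, shape)
        zz = np.arange(lo[0], hi[0])[:, None, None] * voxel[0]
        yy = np.arange(lo[1], hi[1])[None, :, None] * voxel[1]
        xxw = np.arange(lo[2], hi[2])[None, None, :] * voxel[2]
        g = np.exp(
            -(
                ((zz - pos[0]) ** 2) / (2 * sigma[0] ** 2)
                + ((yy - pos[1]) ** 2) / (2 * sigma[1] ** 2)
                + ((xxw - pos[2]) ** 2) / (2 * sigma[2] ** 2)
            )
        )
        tcell[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += spec.cell_amplitude * g

    if spec.noise_sd_tcell > 0:
        tcell += rng.normal(0.0, spec.noise_sd_tcell, size=shape)
    if spec.noise_sd_organoid > 0:
        organoid += rng.normal(0.0, spec.noise_sd_organoid, size=shape)

    stack = validate_calibration(
        CalibratedStack3D(
            channels={"tcell": tcell, "organoid": organoid},
            voxel_size_um=tuple(float(v) for v in voxel),
            chamber_id=f"synthetic-{spec.seed}",
        )
    )
    truth = GroundTruth3D(
        cells=cells,
        organoid_center_um=tuple(float(v) for v in center),
        organoid_semi_axes_um=tuple(float(v) for v in axes),
        organoid_shape=spec.organoid_shape,
        analytic_volume_um3=spec.analytic_volume_um3(),
    )
    return stack, truth
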