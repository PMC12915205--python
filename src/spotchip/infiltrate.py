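"""3D T-cell infiltration quantification in organoid co-culture stacks.

The chamber stack carries two channels: bright T-cell blobs (about 5 µm
across in XY and 10 µm in Z at typical spinning-disk anisotropy) and one
large contiguous organoid body.  The pipeline detects the cells, segments
the organoid and extracts its surface and volume, measures each cell's
signed Euclidean distance to that surface (negative = inside), and counts a
cell as *infiltrated* when its distance lies inside the depth window
[-200 µm, 0 µm] — i.e. in contact with the surface or up to 200 µm deep.

All scales and distances are handled in physical µm, never in raw voxels,
because dz typically differs from dx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import marching_cubes
import trimesh

from .core import (
    CalibratedStack3D,
    DepthWindow,
    DetectionParams3D,
    validate_calibration,
)

__all__ = [
    "CellDetection3D",
    "OrganoidSegmentation",
    "CellDistanceRecord",
    "InfiltrationResult",
    "PooledSummary",
    "detect_tcells_3d",
    "segment_organoid",
    "signed_distance",
    "classify_infiltration",
    "pool_chips",
    "quantify_chamber",
]


@dataclass
class CellDetection3D:
    """One detected T-cell: centroid in µm (z, y, x) plus detection scale."""

    cell_id: int
    centroid_um: tuple[float, float, float]
    peak_intensity: float
    scale_um: tuple[float, float, float]


@dataclass
class OrganoidSegmentation:
    """Binary organoid mask, closed surface mesh, and voxel-count volume."""

    mask: np.ndarray
    surface_mesh: trimesh.Trimesh
    volume_um3: float
    threshold_used: float
    voxel_size_um: tuple[float, float, float]

    @property
    def mesh_volume_um3(self) -> float:
        return float(abs(self.surface_mesh.volume))


@dataclass
class CellDistanceRecord:
    """Signed distance of one cell and its depth-window classification."""

    cell_id: int
    signed_distance_um: float
    classification: str  # infiltrated | outside | excluded_deep


@dataclass
class InfiltrationResult:
    """Per-chamber output of the infiltration quantification."""

    chamber_id: str
    n_cells_total: int
    n_infiltrated: int
    infiltrated_fraction: float
    organoid_volume_um3: float
    records: list[CellDistanceRecord]
    params: dict = field(default_factory=dict)

    def validate(self) -> "InfiltrationResult":
        n_inf = sum(1 for r in self.records if r.classification == "infiltrated")
        if n_inf != self.n_infiltrated:
            raise ValueError(
                f"n_infiltrated ({self.n_infiltrated}) != infiltrated records ({n_inf})"
            )
        if len(self.records) != self.n_cells_total:
            raise ValueError(
                f"n_cells_total ({self.n_cells_total}) != records ({len(self.records)})"
            )
        expect = self.n_infiltrated / self.n_cells_total if self.n_cells_total else 0.0
        if not math.isclose(self.infiltrated_fraction, expect, abs_tol=1e-12):
            raise ValueError("infiltrated_fraction inconsistent with counts")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["records"] = [asdict(r) for r in self.records]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InfiltrationResult":
        d = dict(d)
        d["records"] = [CellDistanceRecord(**r) for r in d["records"]]
        return cls(**d).validate()


@dataclass
class PooledSummary:
    """Across-chip pooled statistics (mean and SEM) for one condition."""

    n_chips: int
    n_infiltrated_per_chip: list[int]
    infiltrated_fraction_per_chip: list[float]
    mean_n_infiltrated: float
    sem_n_infiltrated: float
    mean_infiltrated_fraction: float
    sem_infiltrated_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# detection


def detect_tcells_3d(
    stack: CalibratedStack3D, params: DetectionParams3D | None = None
) -> list[CellDetection3D]:
    """Detect T-cells as local maxima of an anisotropy-matched smoothing.

    The T-cell channel is smoothed with a Gaussian whose per-axis sigma (in
    µm, converted to voxels per axis) matches the expected cell extents via
    sigma = diameter / (2*sqrt(3)).  Local maxima must be separated by at
    least one expected diameter per axis and must exceed the detection
    floor: the ``min_intensity_quantile`` quantile of the smoothed response,
    clamped from below by median + ``noise_floor_sigmas`` robust standard
    deviations so that a blank (noise-only) stack yields no detections.
    """
    if params is None:
        params = DetectionParams3D()
    validate_calibration(stack)
    arr = np.asarray(stack.channel("tcell"), dtype=np.float64)
    voxel = np.asarray(stack.voxel_size_um, dtype=float)
    extent_um = np.asarray(stack.shape) * voxel
    if extent_um[0] < params.z_height_um:
        import warnings

        warnings.warn(
            f"stack depth {extent_um[0]:.1f} µm is thinner than the expected "
            f"cell height {params.z_height_um} µm; detection proceeds",
            stacklevel=2,
        )
    sigmas_um = np.asarray(params.sigmas_um())
    sigmas_vox = sigmas_um / voxel
    resp = ndimage.gaussian_filter(arr, sigma=sigmas_vox, mode="reflect")

    med = float(np.median(resp))
    mad = float(np.median(np.abs(resp - med)))
    robust_sd = 1.4826 * mad
    floor = max(
        float(np.quantile(resp, params.min_intensity_quantile)),
        med + params.noise_floor_sigmas * robust_sd,
    )

    diam_um = np.array(
        [params.z_height_um, params.xy_diameter_um, params.xy_diameter_um]
    )
    # footprint semi-axes of one diameter per axis enforce the minimum
    # separation between surviving maxima
    radius_vox = np.maximum(np.rint(diam_um / voxel).astype(int), 1)
    zz, yy, xx = np.ogrid[
        -radius_vox[0] : radius_vox[0] + 1,
        -radius_vox[1] : radius_vox[1] + 1,
        -radius_vox[2] : radius_vox[2] + 1,
    ]
    footprint = (
        (zz / radius_vox[0]) ** 2 + (yy / radius_vox[1]) ** 2 + (xx / radius_vox[2]) ** 2
    ) <= 1.0

    # reflected padding correlates noise at the faces, inflating the
    # smoothed response there; exclude a 2-sigma margin from peak search
    border = tuple(int(max(1, np.ceil(2.0 * s))) for s in sigmas_vox)
    peaks = peak_local_max(
        resp, footprint=footprint, threshold_abs=floor, exclude_border=border
    )
    detections = []
    cid = 0
    for pz, py, px in peaks:
        if not resp[pz, py, px] > floor:  # strict: rejects flat plateaus
            continue
        cid += 1
        detections.append(
            CellDetection3D(
                cell_id=cid,
                centroid_um=(
                    float(pz * voxel[0]),
                    float(py * voxel[1]),
                    float(px * voxel[2]),
                ),
                peak_intensity=float(arr[pz, py, px]),
                scale_um=tuple(float(s) for s in sigmas_um),
            )
        )
    # deterministic order: by (z, y, x)
    detections.sort(key=lambda d: d.centroid_um)
    for i, d in enumerate(detections, start=1):
        d.cell_id = i
    return detections


# ---------------------------------------------------------------------------
# segmentation


def segment_organoid(
    stack: CalibratedStack3D,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    keep: str = "largest_component",
) -> OrganoidSegmentation:
    """Segment the organoid body and extract its surface and volume.

    The organoid channel is binarized (Otsu by default, or a fixed
    threshold), the largest 26-connected component is kept, internal holes
    are filled, and a closed triangulated surface is extracted at the mask
    boundary with marching cubes in physical µm.  The volume is the voxel
    count times the voxel volume.
    """
    validate_calibration(stack)
    arr = np.asarray(stack.channel("organoid"), dtype=np.float64)
    if threshold_method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold requested but fixed_value is None")
        thr = float(fixed_value)
    elif threshold_method == "otsu":
        thr = float(threshold_otsu(arr))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = arr > thr
    if not binary.any():
        raise ValueError(f"no organoid found: empty mask at threshold {thr:g}")
    if keep != "largest_component":
        raise ValueError(f"unknown keep rule {keep!r}")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        binary = labels == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(binary)

    dz, dy, dx = (float(v) for v in stack.voxel_size_um)
    volume = float(mask.sum()) * dz * dy * dx

    # pad so marching cubes closes bodies touching the stack border
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(dz, dy, dx))
    verts -= np.array([dz, dy, dx])  # undo padding shift
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return OrganoidSegmentation(
        mask=mask,
        surface_mesh=mesh,
        volume_um3=volume,
        threshold_used=thr,
        voxel_size_um=(dz, dy, dx),
    )


# ---------------------------------------------------------------------------
# distances and classification


def signed_distance(
    cells: list[CellDetection3D], seg: OrganoidSegmentation
) -> list[tuple[int, float]]:
    """Shortest Euclidean distance of each cell centroid to the surface, in µm.

    Negative when the centroid lies inside the organoid mask.  Computed with
    an anisotropy-aware Euclidean distance transform: outside voxels carry
    the distance to the nearest organoid voxel, inside voxels minus the
    distance to the nearest background voxel; each centroid reads the field
    at its nearest voxel, so the sign agrees exactly with mask membership.
    """
    mask = seg.mask
    if not mask.any():
        raise ValueError("empty segmentation")
    sampling = seg.voxel_size_um
    d_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    d_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    sd = d_out - d_in
    voxel = np.asarray(sampling, dtype=float)
    out = []
    for cell in cells:
        idx = np.rint(np.asarray(cell.centroid_um) / voxel).astype(int)
        idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
        out.append((cell.cell_id, float(sd[tuple(idx)])))
    return out


def classify_infiltration(
    distances: list[tuple[int, float]],
    window: DepthWindow | None = None,
    chamber_id: str = "",
    organoid_volume_um3: float = float("nan"),
    include_deep: bool = False,
    params: dict | None = None,
) -> InfiltrationResult:
    """Classify each cell against the depth window (inclusive bounds).

    ``infiltrated`` iff d_min <= d <= d_max; ``outside`` iff d > d_max;
    ``excluded_deep`` iff d < d_min.  ``include_deep=True`` merges deep
    cells into the infiltrated class, for analyses that read the lower
    bound as descriptive rather than as an exclusion rule.
    """
    if window is None:
        window = DepthWindow()
    records = []
    for cell_id, d in distances:
        if window.d_min_um <= d <= window.d_max_um:
            cls = "infiltrated"
        elif d > window.d_max_um:
            cls = "outside"
        else:
            cls = "infiltrated" if include_deep else "excluded_deep"
        records.append(CellDistanceRecord(cell_id, float(d), cls))
    n_total = len(records)
    n_inf = sum(1 for r in records if r.classification == "infiltrated")
    result = InfiltrationResult(
        chamber_id=chamber_id,
        n_cells_total=n_total,
        n_infiltrated=n_inf,
        infiltrated_fraction=(n_inf / n_total if n_total else 0.0),
        organoid_volume_um3=float(organoid_volume_um3),
        records=records,
        params={
            **(params or {}),
            "depth_window_um": [window.d_min_um, window.d_max_um],
            "include_deep": include_deep,
        },
    )
    return result.validate()


def pool_chips(
    results: list[InfiltrationResult], min_chips: int = 2
) -> PooledSummary:
    """Pool per-chip results for one condition: mean and SEM across chips.

    SEM is the sample standard deviation (ddof=1) over sqrt(n).  Refuses to
    pool fewer than ``min_chips`` chips (minimum 2 by default), mirroring
    the rule that image data from at least two chips back each condition.
    """
    if len(results) < min_chips:
        raise ValueError(
            f"pooling requires at least {min_chips} chips, got {len(results)}"
        )
    counts = np.array([r.n_infiltrated for r in results], dtype=float)
    fracs = np.array([r.infiltrated_fraction for r in results], dtype=float)
    n = len(results)

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return PooledSummary(
        n_chips=n,
        n_infiltrated_per_chip=[int(c) for c in counts],
        infiltrated_fraction_per_chip=[float(f) for f in fracs],
        mean_n_infiltrated=float(counts.mean()),
        sem_n_infiltrated=sem(counts),
        mean_infiltrated_fraction=float(fracs.mean()),
        sem_infiltrated_fraction=sem(fracs),
    )


# ---------------------------------------------------------------------------
# end-to-end


def quantify_chamber(
    stack: CalibratedStack3D,
    detection_params: DetectionParams3D | None = None,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    window: DepthWindow | None = None,
    include_deep: bool = False,
) -> InfiltrationResult:
    """Full per-chamber quantification.

    Composition: detect_tcells_3d -> segment_organoid -> signed_distance ->
    classify_infiltration, with every parameter echoed into the result.
    """
    if detection_params is None:
        detection_params = DetectionParams3D()
    if window is None:
        window = DepthWindow()
    stage = "validate"
    try:
        validate_calibration(stack)
        stage = "detect_tcells_3d"
        cells = detect_tcells_3d(stack, detection_params)
        stage = "segment_organoid"
        seg = segment_organoid(stack, threshold_method, fixed_value)
        stage = "signed_distance"
        dists = signed_distance(cells, seg)
    except Exception as exc:
        raise type(exc)(f"{stage} failed: {exc}") from exc
    return classify_infiltration(
        dists,
        window,
        chamber_id=stack.chamber_id,
        organoid_volume_um3=seg.volume_um3,
        include_deep=include_deep,
        params={
            "detection": detection_params.model_dump(mode="json"),
            "threshold_method": threshold_method,
            "fixed_value": fixed_value,
            "voxel_size_um": [float(v) for v in stack.voxel_size_um],
        },
    )
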