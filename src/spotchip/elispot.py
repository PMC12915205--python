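"""ELISPOT spot calling: adaptive threshold, cleanup, labeling, size filter.

Each dark spot on an ELISPOT membrane marks one cytokine-secreting cell, so
the per-well spot count measures reactive T-cell frequency.  The pipeline is

    grayscale -> adaptive threshold -> morphological cleanup
              -> connected components -> size filtration -> measurement

and is fully deterministic: identical image + parameters give an identical
report.  The size filter (in µm², inclusive bounds) separates true spots
from small debris and large smears; its range must be stated explicitly in
every report so no silent default leaks into an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .core import (
    CalibratedImage2D,
    ChannelRule,
    Polarity,
    SizeFilterRange,
    validate_calibration,
)

__all__ = [
    "BinaryMask2D",
    "SpotRecord",
    "SpotReport",
    "ElispotParams",
    "adaptive_threshold",
    "morphological_clean",
    "label_components",
    "filter_by_size",
    "measure_spots",
    "count_spots",
]


@dataclass
class BinaryMask2D:
    """Boolean foreground mask plus the parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class SpotRecord:
    """Morphometry of one labeled component.

    ``area_um2 = area_px * pixel_size_um**2`` and
    ``equivalent_diameter_um = 2 * sqrt(area_um2 / pi)`` hold by
    construction; eccentricity is that of the second-moment ellipse.
    """

    spot_id: int
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_px: int
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: float
    eccentricity: float
    accepted: bool = False


class ElispotParams(BaseModel):
    """Full parameter set of the spot-calling pipeline.

    Defaults: local-mean adaptive threshold with a 25 px window radius and
    an offset of 5 intensity units; opening and closing with 1 px disks plus
    hole filling; 8-connectivity; accepted areas in [40, 4000] µm².
    """

    window_radius_px: int = 25
    offset: float = 5.0
    opening_radius_px: int = 1
    closing_radius_px: int = 1
    fill_holes: bool = True
    connectivity: int = 8
    size_filter: SizeFilterRange = SizeFilterRange()
    exclude_border: bool = False
    channel_rule: ChannelRule = ChannelRule.MIN
    histogram_bins: int = 20

    @model_validator(mode="after")
    def _check(self) -> "ElispotParams":
        if self.window_radius_px < 1:
            raise ValueError("window_radius_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.opening_radius_px < 0 or self.closing_radius_px < 0:
            raise ValueError("morphology radii must be >= 0")
        return self


@dataclass
class SpotReport:
    """Per-well output: counts, size statistics, and one record per spot.

    Invariants (enforced by :meth:`validate`):
    ``n_labeled = n_accepted + n_rejected_small + n_rejected_large`` and
    ``n_accepted`` equals the number of accepted records.
    """

    well_id: str
    n_labeled: int
    n_accepted: int
    n_rejected_small: int
    n_rejected_large: int
    size_stats: dict
    size_histogram: dict
    spots: list[SpotRecord]
    params: dict

    def validate(self) -> "SpotReport":
        if self.n_labeled != self.n_accepted + self.n_rejected_small + self.n_rejected_large:
            raise ValueError(
                "count conservation violated: "
                f"{self.n_labeled} != {self.n_accepted} + "
                f"{self.n_rejected_small} + {self.n_rejected_large}"
            )
        n_acc = sum(1 for s in self.spots if s.accepted)
        if n_acc != self.n_accepted:
            raise ValueError(
                f"n_accepted ({self.n_accepted}) != accepted records ({n_acc})"
            )
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spots"] = [asdict(s) for s in self.spots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpotReport":
        d = dict(d)
        d["spots"] = [
            SpotRecord(
                **{
                    **s,
                    "centroid_px": tuple(s["centroid_px"]),
                    "centroid_um": tuple(s["centroid_um"]),
                }
            )
            for s in d["spots"]
        ]
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# stages


def adaptive_threshold(
    image: CalibratedImage2D, window_radius_px: int = 25, offset: float = 5.0
) -> BinaryMask2D:
    """Threshold against the local mean over a (2r+1)² window.

    For dark-spot polarity a pixel is foreground iff its intensity is below
    the local mean minus ``offset``; light-spot polarity flips the
    comparison.  Windows at the boundary use reflected padding.
    """
    validate_calibration(image)
    arr = image.as_float()
    size = 2 * int(window_radius_px) + 1
    if window_radius_px < 1:
        raise ValueError("window_radius_px must be >= 1")
    if size > min(arr.shape):
        raise ValueError(
            f"window ({size} px) larger than image {arr.shape}"
        )
    local_mean = ndimage.uniform_filter(arr, size=size, mode="reflect")
    if image.polarity is Polarity.DARK_SPOTS_ON_LIGHT:
        mask = arr < local_mean - offset
    else:
        mask = arr > local_mean + offset
    return BinaryMask2D(
        mask,
        provenance={
            "stage": "adaptive_threshold",
            "window_radius_px": int(window_radius_px),
            "offset": float(offset),
            "polarity": image.polarity.value,
        },
    )


def morphological_clean(
    mask: BinaryMask2D,
    opening_radius_px: int = 1,
    closing_radius_px: int = 1,
    fill_holes: bool = True,
) -> BinaryMask2D:
    """Opening (remove specks) then closing (bridge gaps) then hole fill.

    Disk-shaped structuring elements; a radius of 0 skips that step.
    """
    out = np.asarray(mask.mask, dtype=bool)
    if opening_radius_px > 0:
        out = ndimage.binary_opening(out, structure=skmorph.disk(opening_radius_px))
    if closing_radius_px > 0:
        out = ndimage.binary_closing(out, structure=skmorph.disk(closing_radius_px))
    if fill_holes:
        out = ndimage.binary_fill_holes(out)
    prov = dict(mask.provenance)
    prov.update(
        stage="morphological_clean",
        opening_radius_px=int(opening_radius_px),
        closing_radius_px=int(closing_radius_px),
        fill_holes=bool(fill_holes),
    )
    return BinaryMask2D(out, prov)


_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def label_components(mask: BinaryMask2D | np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground regions 1..K (0 = background).

    Labels are assigned in raster-scan order of each component's first
    pixel, so the labeling is deterministic.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    arr = mask.mask if isinstance(mask, BinaryMask2D) else np.asarray(mask, dtype=bool)
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, _ = ndimage.label(arr, structure=structure)
    return labels


def filter_by_size(
    labels: np.ndarray, pixel_size_um: float, size_range: SizeFilterRange
) -> tuple[set[int], set[int], set[int]]:
    """Partition labels into (accepted, rejected_small, rejected_large).

    A component is accepted iff ``min_area_um2 <= area <= max_area_um2``
    with inclusive bounds; the three sets are disjoint and exhaustive.
    """
    n = int(labels.max())
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    areas_um2 = counts * float(pixel_size_um) ** 2
    accepted, small, large = set(), set(), set()
    for lab in range(1, n + 1):
        a = areas_um2[lab]
        if a < size_range.min_area_um2:
            small.add(lab)
        elif a > size_range.max_area_um2:
            large.add(lab)
        else:
            accepted.add(lab)
    return accepted, small, large


def measure_spots(
    labels: np.ndarray, image: CalibratedImage2D, pixel_size_um: float | None = None
) -> list[SpotRecord]:
    """One :class:`SpotRecord` per label, in label order.

    Centroids are intensity-unweighted; ``centroid_um`` is the centroid in
    physical (y, x) µm; mean intensity is over member pixels of the source
    image.
    """
    if pixel_size_um is None:
        pixel_size_um = image.pixel_size_um
    arr = image.as_float()
    if labels.shape != arr.shape:
        raise ValueError(f"labels shape {labels.shape} != image shape {arr.shape}")
    records = []
    for prop in skmeasure.regionprops(labels, intensity_image=arr):
        area_px = int(prop.area)
        area_um2 = area_px * pixel_size_um**2
        cy, cx = prop.centroid
        records.append(
            SpotRecord(
                spot_id=int(prop.label),
                centroid_px=(float(cy), float(cx)),
                centroid_um=(float(cy * pixel_size_um), float(cx * pixel_size_um)),
                area_px=area_px,
                area_um2=float(area_um2),
                equivalent_diameter_um=float(2.0 * np.sqrt(area_um2 / np.pi)),
                mean_intensity=float(prop.intensity_mean),
                eccentricity=float(prop.eccentricity),
            )
        )
    return records


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(int(v) for v in np.unique(edge)) - {0}


def count_spots(image: CalibratedImage2D, params: ElispotParams | None = None) -> SpotReport:
    """End-to-end spot calling; returns a validated :class:`SpotReport`."""
    if params is None:
        params = ElispotParams()
    validate_calibration(image)
    try:
        mask = adaptive_threshold(image, params.window_radius_px, params.offset)
        mask = morphological_clean(
            mask, params.opening_radius_px, params.closing_radius_px, params.fill_holes
        )
        labels = label_components(mask, params.connectivity)
        if params.exclude_border:
            drop = _border_labels(labels)
            if drop:
                labels = np.where(np.isin(labels, sorted(drop)), 0, labels)
                # relabel compactly, preserving raster order
                labels = label_components(labels > 0, params.connectivity)
        accepted, small, large = filter_by_size(
            labels, image.pixel_size_um, params.size_filter
        )
        records = measure_spots(labels, image)
    except Exception as exc:  # attach the failing stage name
        raise type(exc)(f"count_spots failed: {exc}") from exc
    for rec in records:
        rec.accepted = rec.spot_id in accepted
    acc_areas = np.array([r.area_um2 for r in records if r.accepted])
    if acc_areas.size:
        size_stats = {
            "min": float(acc_areas.min()),
            "max": float(acc_areas.max()),
            "mean": float(acc_areas.mean()),
            "median": float(np.median(acc_areas)),
        }
    else:
        size_stats = {"min": None, "max": None, "mean": None, "median": None}
    edges = np.linspace(
        params.size_filter.min_area_um2,
        params.size_filter.max_area_um2,
        params.histogram_bins + 1,
    )
    hist, _ = np.histogram(acc_areas, bins=edges)
    report = SpotReport(
        well_id=image.well_id,
        n_labeled=len(records),
        n_accepted=len(accepted),
        n_rejected_small=len(small),
        n_rejected_large=len(large),
        size_stats=size_stats,
        size_histogram={
            "bin_edges_um2": [float(e) for e in edges],
            "counts": [int(c) for c in hist],
        },
        spots=records,
        params={
            **params.model_dump(mode="json"),
            "pixel_size_um": image.pixel_size_um,
            "polarity": image.polarity.value,
        },
    )
    return report.validate()
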