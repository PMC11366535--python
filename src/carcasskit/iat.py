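"""Image-analysis traits of carcass cross-sections.

Given a grayscale cross-section image, a region label map and a linear
calibration (pixels per cm), this module computes, per muscle: area (cm²),
marbling percentage (%), coarseness index (%) and the new fineness index
(total marbling-particle perimeter divided by the square root of the muscle
area — higher means finer marbling); thickness (mm) for the two flat muscles
(*M. trapezius dorsi*, *M. latissimus dorsi*); and for the target field:
area, thickness, intermuscular-fat (IF) and subcutaneous-fat (SF) areas and
area percentages.

Thickness is measured along the second inertia principal axis (the
eigenvector of the region's second central moment matrix with the smaller
eigenvalue) through the centroid; if that line leaves and re-enters the
region, the in-region chord lengths are summed.

Marbling particles are connected components (8-connectivity) of
above-threshold pixels inside the muscle mask, components smaller than a
minimum size dropped.  The commercial grading software's segmentation is not
public, so the threshold rule, connectivity, minimum size and perimeter
estimator are explicit settings recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import perimeter as crack_perimeter
from skimage.measure import regionprops

__all__ = [
    "SegmentationSettings",
    "MarblingParticle",
    "RegionGeometry",
    "MarblingIndices",
    "TargetFieldTraits",
    "segment_particles",
    "particles_from_mask",
    "region_geometry",
    "marbling_indices",
    "target_field_traits",
    "extract_iat_table",
    "MUSCLE_NAMES",
    "TRAIT_COLUMNS",
]

# label-map conventions shared with the phantom generator
LABEL_BACKGROUND = 0
MUSCLE_LABELS = (1, 2, 3, 4, 5)
LABEL_IF = 6
LABEL_SF = 7
LABEL_OTHER = 8

MUSCLE_NAMES = {
    1: "M. longissimus dorsi",
    2: "M. semispinalis capitis",
    3: "M. semispinalis dorsi",
    4: "M. trapezius dorsi",
    5: "M. latissimus dorsi",
}
#: muscles whose thickness is reported
THICKNESS_MUSCLES = (4, 5)

_MUSCLE_TRAITS = (
    "Area (cm2)",
    "Marbling percentage (%)",
    "New fineness index",
    "Coarseness index (%)",
)
_FIELD_TRAITS = (
    "Area (cm2)",
    "Thickness (mm)",
    "IF area (cm2)",
    "IF area percentage (%)",
    "SF area (cm2)",
    "SF area percentage (%)",
)


def _trait_columns() -> list[str]:
    cols = []
    for lab in MUSCLE_LABELS:
        name = MUSCLE_NAMES[lab]
        for t in _MUSCLE_TRAITS:
            cols.append(f"{name}: {t}")
        if lab in THICKNESS_MUSCLES:
            cols.append(f"{name}: Thickness (mm)")
    cols += [f"Target field: {t}" for t in _FIELD_TRAITS]
    return cols


#: the 28 image-trait column names, in report order
TRAIT_COLUMNS = _trait_columns()


@dataclass
class SegmentationSettings:
    """Marbling segmentation parameters.

    ``threshold=None`` selects Otsu's threshold on the within-mask pixels
    (for noisy images); a fixed value is appropriate for noiseless renders.
    ``perimeter_mode`` is ``"crack"`` (boundary crack length with the
    standard isotropic weights) or ``"pixel"`` (raw boundary-pixel count).
    """

    threshold: float | None = 140.0
    min_size_px: int = 4
    connectivity: int = 2  # scikit-image convention: 2 == 8-connectivity
    perimeter_mode: str = "crack"
    coarse_threshold_cm2: float = 0.5

    def __post_init__(self) -> None:
        if self.perimeter_mode not in ("crack", "pixel"):
            raise ValueError("perimeter_mode must be 'crack' or 'pixel'")
        if self.coarse_threshold_cm2 <= 0:
            raise ValueError("coarse_threshold_cm2 must be positive")


@dataclass
class MarblingParticle:
    """One connected marbling particle inside a muscle."""

    n_pixels: int
    area_cm2: float
    perimeter_cm: float

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0 or self.perimeter_cm <= 0:
            raise ValueError("particle area and perimeter must be positive")


@dataclass
class RegionGeometry:
    """Area, centroid, inertia principal axes and thickness of a region."""

    area_cm2: float
    centroid: tuple
    first_axis: np.ndarray
    second_axis: np.ndarray
    thickness_mm: float


@dataclass
class MarblingIndices:
    marbling_percentage: float
    coarseness_index: float
    new_fineness_index: float


@dataclass
class TargetFieldTraits:
    area_cm2: float
    thickness_mm: float
    if_area_cm2: float
    if_area_percentage: float
    sf_area_cm2: float
    sf_area_percentage: float


def _perimeter_px(mask: np.ndarray, mode: str) -> float:
    if mode == "crack":
        return float(crack_perimeter(mask, neighborhood=4))
    # raw count of object pixels 4-adjacent to background
    padded = np.pad(mask, 1)
    inner = (
        padded[1:-1, 1:-1]
        & padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return float(np.count_nonzero(padded[1:-1, 1:-1] & ~inner))


def particles_from_mask(
    marbling_mask: np.ndarray,
    px_per_cm: float,
    settings: SegmentationSettings | None = None,
) -> list[MarblingParticle]:
    """Connected-component particles of an already-binary marbling mask."""
    settings = settings or SegmentationSettings()
    labels = cc_label(marbling_mask, connectivity=settings.connectivity)
    px_area = px_per_cm**2
    out = []
    for prop in regionprops(labels):
        if prop.num_pixels < settings.min_size_px:
            continue
        sub = labels[prop.slice] == prop.label
        out.append(
            MarblingParticle(
                n_pixels=int(prop.num_pixels),
                area_cm2=prop.num_pixels / px_area,
                perimeter_cm=_perimeter_px(sub, settings.perimeter_mode) / px_per_cm,
            )
        )
    return out


def segment_particles(
    image: np.ndarray,
    muscle_mask: np.ndarray,
    px_per_cm: float,
    settings: SegmentationSettings | None = None,
) -> list[MarblingParticle]:
    """Threshold-based marbling segmentation inside one muscle mask."""
    settings = settings or SegmentationSettings()
    if image.shape != muscle_mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not muscle_mask.any():
        raise ValueError("empty muscle mask")
    thr = settings.threshold
    if thr is None:
        vals = image[muscle_mask]
        thr = threshold_otsu(vals) if vals.min() != vals.max() else np.inf
    else:
        lo, hi = float(image.min()), float(image.max())
        if not (image.dtype == np.uint8 and 0 <= thr <= 255) and not lo <= thr <= hi:
            raise ValueError(f"threshold {thr} outside intensity range [{lo}, {hi}]")
    binary = (np.asarray(image, dtype=float) >= thr) & muscle_mask
    return particles_from_mask(binary, px_per_cm, settings)


def _chord_length_px(mask: np.ndarray, point: np.ndarray, direction: np.ndarray) -> float:
    """Exact length of line ∩ (union of mask pixel unit squares).

    The line through ``point`` with unit ``direction`` is clipped against
    each mask pixel's square [r-1/2, r+1/2] x [c-1/2, c+1/2]; the measure of
    the union of the resulting parameter intervals is the summed chord
    length, robust to concavities (re-entrant lines sum their segments).
    """
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return 0.0
    lo = np.full(rr.shape, -np.inf)
    hi = np.full(rr.shape, np.inf)
    keep = np.ones(rr.shape, dtype=bool)
    for coords, p0, d0 in ((rr, point[0], direction[0]), (cc, point[1], direction[1])):
        if abs(d0) > 1e-12:
            t1 = (coords - 0.5 - p0) / d0
            t2 = (coords + 0.5 - p0) / d0
            lo = np.maximum(lo, np.minimum(t1, t2))
            hi = np.minimum(hi, np.maximum(t1, t2))
        else:
            keep &= np.abs(coords - p0) <= 0.5
    keep &= hi > lo
    if not keep.any():
        return 0.0
    intervals = np.column_stack([lo[keep], hi[keep]])
    intervals = intervals[np.argsort(intervals[:, 0])]
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
        else:
            cur_hi = max(cur_hi, b)
    total += cur_hi - cur_lo
    return float(total)


def region_geometry(mask: np.ndarray, px_per_cm: float) -> RegionGeometry:
    """Area, centroid, inertia principal axes and second-axis thickness.

    Axes are the eigenvectors of the 2x2 second central moment matrix of the
    pixel coordinates; the first axis carries the larger eigenvalue.  For a
    tie (e.g. a disk) the image row direction is taken as the first axis.
    Disconnected masks are measured on their union with a warning.
    """
    if px_per_cm <= 0:
        raise ValueError("calibration must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    if cc_label(mask, connectivity=2).max() > 1:
        warnings.warn("disconnected region: geometry computed on the union", stacklevel=2)
    rr, cc = np.nonzero(mask)
    centroid = np.array([rr.mean(), cc.mean()])
    dr, dc = rr - centroid[0], cc - centroid[1]
    m = np.array([[np.mean(dr * dr), np.mean(dr * dc)], [np.mean(dr * dc), np.mean(dc * dc)]])
    evals, evecs = np.linalg.eigh(m)  # ascending
    if np.isclose(evals[0], evals[1]):
        first = np.array([1.0, 0.0])
        second = np.array([0.0, 1.0])
    else:
        first = evecs[:, 1]
        second = evecs[:, 0]
    chord_px = _chord_length_px(mask, centroid, second)
    return RegionGeometry(
        area_cm2=rr.size / px_per_cm**2,
        centroid=(float(centroid[0]), float(centroid[1])),
        first_axis=first,
        second_axis=second,
        thickness_mm=chord_px / px_per_cm * 10.0,
    )


def marbling_indices(
    particles: list[MarblingParticle],
    muscle_area_cm2: float,
    coarse_threshold_cm2: float = 0.5,
) -> MarblingIndices:
    """Marbling %, coarseness index and new fineness index for one muscle.

    marbling% = 100 * (sum of particle areas) / muscle area;
    coarseness% counts only particles at least ``coarse_threshold_cm2`` big;
    fineness = (total particle perimeter, cm) / sqrt(muscle area, cm²).
    """
    if muscle_area_cm2 <= 0:
        raise ValueError("muscle area must be positive")
    if coarse_threshold_cm2 <= 0:
        raise ValueError("coarse threshold must be positive")
    total = sum(p.area_cm2 for p in particles)
    coarse = sum(p.area_cm2 for p in particles if p.area_cm2 >= coarse_threshold_cm2)
    perim = sum(p.perimeter_cm for p in particles)
    return MarblingIndices(
        marbling_percentage=100.0 * total / muscle_area_cm2,
        coarseness_index=100.0 * coarse / muscle_area_cm2,
        new_fineness_index=perim / np.sqrt(muscle_area_cm2),
    )


def target_field_traits(
    label_map: np.ndarray,
    target_polygon: np.ndarray,
    px_per_cm: float,
) -> TargetFieldTraits:
    """Field area/thickness and IF/SF areas inside the target-field polygon.

    ``target_polygon`` is an (k, 2) array of (row, col) pixel coordinates.
    """
    poly = np.asarray(target_polygon, dtype=float)
    h, w = label_map.shape
    if poly[:, 0].max() < 0 or poly[:, 1].max() < 0 or poly[:, 0].min() > h or poly[:, 1].min() > w:
        raise ValueError("target polygon lies outside the image")
    field = polygon2mask(label_map.shape, poly)
    if not field.any():
        raise ValueError("target polygon encloses no pixels")
    geom = region_geometry(field, px_per_cm)
    px_area = px_per_cm**2
    n_field = int(np.count_nonzero(field))
    n_if = int(np.count_nonzero(field & (label_map == LABEL_IF)))
    n_sf = int(np.count_nonzero(field & (label_map == LABEL_SF)))
    return TargetFieldTraits(
        area_cm2=n_field / px_area,
        thickness_mm=geom.thickness_mm,
        if_area_cm2=n_if / px_area,
        if_area_percentage=100.0 * n_if / n_field,
        sf_area_cm2=n_sf / px_area,
        sf_area_percentage=100.0 * n_sf / n_field,
    )


def extract_single(
    image: np.ndarray,
    label_map: np.ndarray,
    target_polygon: np.ndarray,
    px_per_cm: float,
    settings: SegmentationSettings | None = None,
) -> dict:
    """Trait dictionary (the 28 TRAIT_COLUMNS) for one carcass image.

    A muscle label absent from the map yields NaN for that muscle's traits
    (an explicit absent marker, not zero).
    """
    settings = settings or SegmentationSettings()
    row: dict = {c: np.nan for c in TRAIT_COLUMNS}
    for lab in MUSCLE_LABELS:
        name = MUSCLE_NAMES[lab]
        mask = label_map == lab
        if not mask.any():
            continue
        geom = region_geometry(mask, px_per_cm)
        particles = segment_particles(image, mask, px_per_cm, settings)
        idx = marbling_indices(particles, geom.area_cm2, settings.coarse_threshold_cm2)
        row[f"{name}: Area (cm2)"] = geom.area_cm2
        row[f"{name}: Marbling percentage (%)"] = idx.marbling_percentage
        row[f"{name}: New fineness index"] = idx.new_fineness_index
        row[f"{name}: Coarseness index (%)"] = idx.coarseness_index
        if lab in THICKNESS_MUSCLES:
            row[f"{name}: Thickness (mm)"] = geom.thickness_mm
    field = target_field_traits(label_map, target_polygon, px_per_cm)
    row["Target field: Area (cm2)"] = field.area_cm2
    row["Target field: Thickness (mm)"] = field.thickness_mm
    row["Target field: IF area (cm2)"] = field.if_area_cm2
    row["Target field: IF area percentage (%)"] = field.if_area_percentage
    row["Target field: SF area (cm2)"] = field.sf_area_cm2
    row["Target field: SF area percentage (%)"] = field.sf_area_percentage
    return row


def extract_iat_table(inputs, settings: SegmentationSettings | None = None) -> pd.DataFrame:
    """One row of the 28 image traits per carcass.

    ``inputs`` is an iterable of phantoms (anything with ``image``,
    ``label_map``, ``target_polygon_px`` and ``px_per_cm`` attributes) or of
    ``(image, label_map, target_polygon, px_per_cm)`` tuples.
    """
    rows = []
    for item in inputs:
        if hasattr(item, "label_map"):
            args = (item.image, item.label_map, item.target_polygon_px, item.px_per_cm)
        else:
            args = item
        rows.append(extract_single(*args, settings=settings))
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)
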