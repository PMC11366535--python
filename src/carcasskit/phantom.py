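"""Synthetic carcass cross-section phantoms with exact ground truth.

A phantom is a rasterized rib-cross-section: five labelled muscles (the
image-analysis targets: *M. longissimus dorsi*, *M. semispinalis capitis*,
*M. semispinalis dorsi*, *M. trapezius dorsi*, *M. latissimus dorsi*), an
explicit target-field polygon, a subcutaneous-fat band along the field
boundary, intermuscular-fat channels around the muscles, and marbling
particles inside each muscle.

All geometry is specified in centimetres and only rasterized at the
configured calibration, so the same seed renders the identical continuous
phantom at any resolution (used by the scale-invariance checks).  Marbling
particles are axis-unaligned ellipses with Poisson counts and log-normal
areas; overlapping particles merge by union, matching connected-component
extraction.  Ground truth is computed from the rasterized masks with the
same trait definitions as the extraction module, so extraction on a
noiseless phantom reproduces it exactly for pixel-count traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.draw import polygon2mask

from . import iat
from .iat import (
    LABEL_IF,
    LABEL_OTHER,
    LABEL_SF,
    MUSCLE_LABELS,
    MUSCLE_NAMES,
    THICKNESS_MUSCLES,
    TRAIT_COLUMNS,
    SegmentationSettings,
    marbling_indices,
    particles_from_mask,
    region_geometry,
    target_field_traits,
)

__all__ = [
    "MarblingSpec",
    "MuscleSpec",
    "PhantomConfig",
    "CarcassPhantom",
    "PhantomConfigError",
    "default_config",
    "generate_phantom",
    "ground_truth_traits",
]


class PhantomConfigError(ValueError):
    pass


@dataclass
class MarblingSpec:
    """Particle process for one muscle.

    ``particles_per_cm2`` is the Poisson intensity; particle areas are
    log-normal with the given median (cm²) and log-SD.  A larger median at
    matched coverage gives coarser marbling.
    """

    particles_per_cm2: float = 2.5
    median_area_cm2: float = 0.2
    log_area_sd: float = 0.8
    aspect_range: tuple = (1.0, 3.0)

    def __post_init__(self) -> None:
        vals = (self.particles_per_cm2, self.median_area_cm2, self.log_area_sd)
        if not all(np.isfinite(vals)) or self.particles_per_cm2 < 0 or self.median_area_cm2 <= 0:
            raise PhantomConfigError("marbling parameters must be finite and positive")

    def with_median_area(self, median_cm2: float) -> "MarblingSpec":
        """Change particle size keeping the expected coverage fixed."""
        scale = self.median_area_cm2 / median_cm2
        return replace(
            self,
            median_area_cm2=median_cm2,
            particles_per_cm2=self.particles_per_cm2 * scale,
        )


@dataclass
class MuscleSpec:
    """An elliptical muscle region in cm coordinates.

    ``angle_deg`` rotates the first semi-axis counterclockwise from the
    column (horizontal) axis.
    """

    label: int
    center_cm: tuple
    semi_axes_cm: tuple
    angle_deg: float = 0.0
    marbling: MarblingSpec = field(default_factory=MarblingSpec)

    @property
    def area_cm2(self) -> float:
        return float(np.pi * self.semi_axes_cm[0] * self.semi_axes_cm[1])


@dataclass
class PhantomConfig:
    """Full phantom specification; geometry in cm, raster size in pixels."""

    height_px: int = 750
    width_px: int = 1000
    px_per_cm: float = 25.0
    muscles: tuple = ()
    field_polygon_cm: np.ndarray = None
    sf_band_mm: float = 10.0
    if_channel_mm: float = 6.0
    lean_intensity: int = 80
    fat_intensity: int = 200
    other_intensity: int = 110
    background_intensity: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise PhantomConfigError("calibration (px per cm) must be positive")
        if self.field_polygon_cm is not None:
            self.field_polygon_cm = np.asarray(self.field_polygon_cm, dtype=float)

    def with_scale(self, factor: float) -> "PhantomConfig":
        """Same continuous phantom rendered at ``factor`` times the resolution."""
        return replace(
            self,
            height_px=int(round(self.height_px * factor)),
            width_px=int(round(self.width_px * factor)),
            px_per_cm=self.px_per_cm * factor,
        )


@dataclass
class CarcassPhantom:
    """Rendered phantom: image, label map, marbling mask and ground truth."""

    image: np.ndarray
    label_map: np.ndarray
    marbling_mask: np.ndarray
    target_polygon_px: np.ndarray
    px_per_cm: float
    seed: int
    ground_truth: dict

    @property
    def ground_truth_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-region-trait view of the ground truth."""
        rows = []
        for col in TRAIT_COLUMNS:
            region, trait = col.split(": ", 1)
            rows.append({"region": region, "trait": trait, "value": self.ground_truth[col]})
        return pd.DataFrame(rows)


def default_config(seed: int = 0, marbling: MarblingSpec | None = None) -> PhantomConfig:
    """A cross-section phantom at realistic trait scale.

    Region sizes follow typical Japanese Black carcass values: rib eye
    (longissimus) ~62 cm², target field ~560 cm², IF ~- and SF bands sized
    to give fat percentages in the mid-teens.
    """
    mb = marbling or MarblingSpec()
    muscles = (
        MuscleSpec(1, (18.0, 22.0), (5.5, 3.6), 15.0, mb),
        MuscleSpec(2, (10.0, 30.5), (2.7, 1.7), 45.0, mb),
        MuscleSpec(3, (11.0, 13.5), (4.4, 2.8), 10.0, mb),
        MuscleSpec(4, (5.5, 18.0), (9.4, 1.8), 5.0, mb),
        MuscleSpec(5, (25.0, 13.0), (7.8, 1.8), 175.0, mb),
    )
    polygon = np.array(
        [
            [2.0, 4.0],
            [2.0, 30.0],
            [10.0, 36.0],
            [24.0, 36.0],
            [28.5, 24.0],
            [28.5, 8.0],
            [16.0, 2.0],
        ]
    )
    return PhantomConfig(muscles=muscles, field_polygon_cm=polygon, seed=seed)


def _ellipse_mask(shape, center_px, semi_px, angle_deg) -> np.ndarray:
    """Rasterize a rotated ellipse by the pixel-centre inclusion test."""
    h, w = shape
    a, b = semi_px
    rad = np.deg2rad(angle_deg)
    extent = max(a, b)
    r0 = max(int(np.floor(center_px[0] - extent)) - 1, 0)
    r1 = min(int(np.ceil(center_px[0] + extent)) + 2, h)
    c0 = max(int(np.floor(center_px[1] - extent)) - 1, 0)
    c1 = min(int(np.ceil(center_px[1] + extent)) + 2, w)
    mask = np.zeros(shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center_px[0]
    dc = cc - center_px[1]
    # x along the angle direction (columns grow with x, rows with -y)
    x = dc * np.cos(rad) + dr * np.sin(rad)
    y = -dc * np.sin(rad) + dr * np.cos(rad)
    mask[r0:r1, c0:c1] = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    return mask


def _sample_particles(muscle: MuscleSpec, rng) -> list:
    """Continuous (cm-space) marbling particle ellipses for one muscle."""
    mb = muscle.marbling
    count = rng.poisson(mb.particles_per_cm2 * muscle.area_cm2)
    mu = np.log(mb.median_area_cm2)
    out = []
    rad = np.deg2rad(muscle.angle_deg)
    for _ in range(count):
        # uniform point in the muscle ellipse via the unit disk
        theta = rng.uniform(0.0, 2 * np.pi)
        radius = np.sqrt(rng.uniform())
        unit = radius * np.array([np.cos(theta), np.sin(theta)])
        xy = unit * muscle.semi_axes_cm  # (x along angle, y perpendicular)
        # rotate (x, y) back to (dc, dr)
        dc = xy[0] * np.cos(rad) - xy[1] * np.sin(rad)
        dr = xy[0] * np.sin(rad) + xy[1] * np.cos(rad)
        center = (muscle.center_cm[0] + dr, muscle.center_cm[1] + dc)
        area = np.exp(rng.normal(mu, mb.log_area_sd))
        aspect = rng.uniform(*mb.aspect_range)
        b = np.sqrt(area / (np.pi * aspect))
        a = aspect * b
        angle = rng.uniform(0.0, 180.0)
        out.append((center, (a, b), angle))
    return out


def generate_phantom(cfg: PhantomConfig, seed: int | None = None) -> CarcassPhantom:
    """Render a phantom; deterministic for a fixed config and seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s = cfg.px_per_cm
    shape = (cfg.height_px, cfg.width_px)

    field = polygon2mask(shape, cfg.field_polygon_cm * s)
    if not field.any():
        raise PhantomConfigError("target-field polygon encloses no pixels")

    muscle_masks = {}
    for m in cfg.muscles:
        mask = _ellipse_mask(
            shape,
            (m.center_cm[0] * s, m.center_cm[1] * s),
            (m.semi_axes_cm[0] * s, m.semi_axes_cm[1] * s),
            m.angle_deg,
        )
        muscle_masks[m.label] = mask
    union = np.zeros(shape, dtype=bool)
    for m in cfg.muscles:
        if (union & muscle_masks[m.label]).any():
            raise PhantomConfigError(f"muscle {m.label} overlaps another muscle region")
        union |= muscle_masks[m.label]

    # SF band: field pixels within the band width of the field boundary
    sf = np.zeros(shape, dtype=bool)
    if cfg.sf_band_mm > 0:
        dist_in = distance_transform_edt(field)
        sf = field & (dist_in <= cfg.sf_band_mm / 10.0 * s) & ~union
    # IF channels: field pixels within the channel width of a muscle
    ifat = np.zeros(shape, dtype=bool)
    if cfg.if_channel_mm > 0:
        dist_muscle = distance_transform_edt(~union)
        ifat = field & (dist_muscle <= cfg.if_channel_mm / 10.0 * s) & ~union & ~sf

    label_map = np.zeros(shape, dtype=np.uint16)
    label_map[field] = LABEL_OTHER
    label_map[ifat] = LABEL_IF
    label_map[sf] = LABEL_SF
    for m in cfg.muscles:
        label_map[muscle_masks[m.label]] = m.label

    # marbling: continuous particle processes, rasterized and clipped
    marbling = np.zeros(shape, dtype=bool)
    for m in cfg.muscles:
        particles = _sample_particles(m, rng)
        placed = 0
        for center_cm, semi_cm, angle in particles:
            pm = _ellipse_mask(
                shape,
                (center_cm[0] * s, center_cm[1] * s),
                (semi_cm[0] * s, semi_cm[1] * s),
                angle,
            )
            pm &= muscle_masks[m.label]
            if pm.any():
                marbling |= pm
                placed += 1
        if particles and placed == 0:
            warnings.warn(
                f"no marbling particle fit inside muscle {m.label}; zero particles",
                stacklevel=2,
            )

    image = np.full(shape, cfg.background_intensity, dtype=float)
    image[field] = cfg.other_intensity
    image[union] = cfg.lean_intensity
    image[marbling | ifat | sf] = cfg.fat_intensity
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    phantom = CarcassPhantom(
        image=image,
        label_map=label_map,
        marbling_mask=marbling,
        target_polygon_px=cfg.field_polygon_cm * s,
        px_per_cm=s,
        seed=seed,
        ground_truth={},
    )
    phantom.ground_truth = ground_truth_traits(phantom)
    return phantom


def ground_truth_traits(
    phantom: CarcassPhantom, settings: SegmentationSettings | None = None
) -> dict:
    """Trait table recomputed from the rasterized masks.

    Uses the extraction module's own definitions (connected components of
    the marbling mask, same minimum size, same perimeter estimator), so it is
    the exact oracle for round-trip tests on noiseless renders.  A missing
    muscle label yields NaN, not zero.
    """
    settings = settings or SegmentationSettings()
    row: dict = {c: np.nan for c in TRAIT_COLUMNS}
    for lab in MUSCLE_LABELS:
        name = MUSCLE_NAMES[lab]
        mask = phantom.label_map == lab
        if not mask.any():
            continue
        geom = region_geometry(mask, phantom.px_per_cm)
        particles = particles_from_mask(
            phantom.marbling_mask & mask, phantom.px_per_cm, settings
        )
        idx = marbling_indices(particles, geom.area_cm2, settings.coarse_threshold_cm2)
        row[f"{name}: Area (cm2)"] = geom.area_cm2
        row[f"{name}: Marbling percentage (%)"] = idx.marbling_percentage
        row[f"{name}: New fineness index"] = idx.new_fineness_index
        row[f"{name}: Coarseness index (%)"] = idx.coarseness_index
        if lab in THICKNESS_MUSCLES:
            row[f"{name}: Thickness (mm)"] = geom.thickness_mm
    fld = target_field_traits(phantom.label_map, phantom.target_polygon_px, phantom.px_per_cm)
    row["Target field: Area (cm2)"] = fld.area_cm2
    row["Target field: Thickness (mm)"] = fld.thickness_mm
    row["Target field: IF area (cm2)"] = fld.if_area_cm2
    row["Target field: IF area percentage (%)"] = fld.if_area_percentage
    row["Target field: SF area (cm2)"] = fld.sf_area_cm2
    row["Target field: SF area percentage (%)"] = fld.sf_area_percentage
    return row
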