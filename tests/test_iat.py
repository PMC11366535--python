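import numpy as np
import pytest

from carcasskit.iat import (
    MarblingParticle,
    SegmentationSettings,
    extract_iat_table,
    marbling_indices,
    region_geometry,
    segment_particles,
    target_field_traits,
    TRAIT_COLUMNS,
)
from carcasskit.phantom import MarblingSpec, default_config, generate_phantom


def _rect_mask(h, w, rows, cols):
    m = np.zeros((h, w), dtype=bool)
    m[rows[0]:rows[1], cols[0]:cols[1]] = True
    return m


class TestSegmentation:
    settings = SegmentationSettings(threshold=140.0)

    def test_uniform_lean_muscle_has_no_particles(self):
        img = np.full((30, 30), 80, dtype=np.uint8)
        mask = _rect_mask(30, 30, (5, 25), (5, 25))
        assert segment_particles(img, mask, 10.0, self.settings) == []

    def test_single_bright_square_is_one_particle(self):
        img = np.full((30, 30), 80, dtype=np.uint8)
        img[10:20, 10:20] = 200
        mask = np.ones((30, 30), dtype=bool)
        parts = segment_particles(img, mask, 10.0, self.settings)
        assert len(parts) == 1
        assert parts[0].n_pixels == 100
        assert parts[0].area_cm2 == pytest.approx(1.0)

    def test_lean_gap_separates_particles(self):
        img = np.full((20, 20), 80, dtype=np.uint8)
        img[2:6, 2:6] = 200
        img[2:6, 7:11] = 200  # one-pixel lean gap at column 6
        mask = np.ones((20, 20), dtype=bool)
        parts = segment_particles(img, mask, 10.0, self.settings)
        assert len(parts) == 2

    def test_min_size_drops_specks(self):
        img = np.full((20, 20), 80, dtype=np.uint8)
        img[5, 5] = 200  # single pixel, below the 4-px minimum
        mask = np.ones((20, 20), dtype=bool)
        assert segment_particles(img, mask, 10.0, self.settings) == []

    def test_empty_mask_raises(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="empty"):
            segment_particles(img, np.zeros((10, 10), bool), 10.0, self.settings)

    def test_threshold_outside_range_raises(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        mask = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="threshold"):
            segment_particles(img, mask, 10.0, SegmentationSettings(threshold=300.0))


class TestRegionGeometry:
    def test_rectangle_area_and_thickness(self):
        mask = _rect_mask(20, 60, (5, 15), (10, 50))  # 10 x 40 px
        geom = region_geometry(mask, 10.0)
        assert geom.area_cm2 == pytest.approx(4.0)
        assert geom.thickness_mm == pytest.approx(10.0, abs=1e-9)

    def test_disk_thickness_is_a_diameter(self):
        rr, cc = np.mgrid[0:120, 0:120]
        mask = (rr - 60.0) ** 2 + (cc - 60.0) ** 2 <= 50.0**2
        geom = region_geometry(mask, 10.0)
        # 1 px tolerance on the rasterized diameter (1 px = 1 mm here)
        assert abs(geom.thickness_mm - 100.0) <= 1.0 + 1e-9

    def test_rotated_rectangle_thickness(self):
        rad = np.deg2rad(30.0)
        rr, cc = np.mgrid[0:100, 0:100]
        x = (cc - 50) * np.cos(rad) + (rr - 50) * np.sin(rad)
        y = -(cc - 50) * np.sin(rad) + (rr - 50) * np.cos(rad)
        mask = (np.abs(x) <= 20) & (np.abs(y) <= 5)
        geom = region_geometry(mask, 10.0)
        assert abs(geom.thickness_mm - 10.0) <= 2.0  # within 2 px of the short side

    def test_rotation_by_90_swaps_axes_and_keeps_area(self):
        mask = _rect_mask(30, 60, (5, 15), (10, 50))
        g1 = region_geometry(mask, 10.0)
        g2 = region_geometry(mask.T.copy(), 10.0)
        assert g1.area_cm2 == g2.area_cm2
        assert abs(np.dot(g1.first_axis, g2.second_axis)) == pytest.approx(1.0)
        assert g1.thickness_mm == pytest.approx(g2.thickness_mm)

    def test_thickness_bounded_by_diameter(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a, b = rng.uniform(5, 30, size=2)
            ang = rng.uniform(0, np.pi)
            rr, cc = np.mgrid[0:100, 0:100]
            x = (cc - 50) * np.cos(ang) + (rr - 50) * np.sin(ang)
            y = -(cc - 50) * np.sin(ang) + (rr - 50) * np.cos(ang)
            mask = (x / a) ** 2 + (y / b) ** 2 <= 1
            geom = region_geometry(mask, 10.0)
            diameter_px = 2.0 * max(a, b) + 2.0  # continuous diameter + raster slack
            assert geom.thickness_mm <= diameter_px  # 1 px == 1 mm at 10 px/cm

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            region_geometry(np.zeros((5, 5), bool), 10.0)

    def test_disconnected_mask_warns(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[7:9, 7:9] = True
        with pytest.warns(UserWarning, match="disconnected"):
            region_geometry(mask, 10.0)


class TestMarblingIndices:
    def test_marbling_percentage_ratio(self):
        # 120 marbling px in a 480 px muscle at 10 px/cm
        parts = [MarblingParticle(120, 1.2, 5.0)]
        idx = marbling_indices(parts, 4.8, coarse_threshold_cm2=0.5)
        assert idx.marbling_percentage == pytest.approx(25.0)

    def test_fineness_closed_form(self):
        # unit square particle: perimeter 4 cm, muscle 64 cm^2
        parts = [MarblingParticle(100, 1.0, 4.0)]
        idx = marbling_indices(parts, 64.0)
        assert idx.new_fineness_index == pytest.approx(0.5)

    def test_coarseness_counts_only_large_particles(self):
        parts = [
            MarblingParticle(60, 0.6, 3.0),
            MarblingParticle(30, 0.3, 2.0),
            MarblingParticle(20, 0.2, 2.0),
        ]
        idx = marbling_indices(parts, 10.0, coarse_threshold_cm2=0.5)
        assert idx.coarseness_index == pytest.approx(6.0)
        assert idx.coarseness_index <= idx.marbling_percentage

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            marbling_indices([], 10.0, coarse_threshold_cm2=0.0)


class TestTargetField:
    def test_fat_percentages(self):
        labels = np.zeros((120, 120), dtype=np.uint16)
        labels[10:110, 10:110] = 8  # other tissue inside the field
        labels[10:20, 10:110] = 6  # IF: 1,000 px
        labels[20:25, 10:110] = 7  # SF: 500 px
        poly = np.array([[9.5, 9.5], [9.5, 109.5], [109.5, 109.5], [109.5, 9.5]])
        t = target_field_traits(labels, poly, 10.0)
        assert t.area_cm2 == pytest.approx(100.0)
        assert t.if_area_cm2 == pytest.approx(10.0)
        assert t.if_area_percentage == pytest.approx(10.0)
        assert t.sf_area_cm2 == pytest.approx(5.0)
        assert t.sf_area_percentage == pytest.approx(5.0)

    def test_no_fat_labels_gives_zero(self):
        labels = np.full((50, 50), 8, dtype=np.uint16)
        poly = np.array([[0, 0], [0, 49], [49, 49], [49, 0]], dtype=float)
        t = target_field_traits(labels, poly, 10.0)
        assert t.if_area_cm2 == 0.0 and t.sf_area_cm2 == 0.0

    def test_polygon_outside_image_raises(self):
        labels = np.zeros((20, 20), dtype=np.uint16)
        poly = np.array([[-50, -50], [-50, -40], [-40, -40]], dtype=float)
        with pytest.raises(ValueError, match="polygon"):
            target_field_traits(labels, poly, 10.0)


class TestExtractTable:
    def test_batch_shape(self, small_cfg):
        phantoms = [generate_phantom(small_cfg, seed=s) for s in range(3)]
        table = extract_iat_table(phantoms)
        assert table.shape == (3, 28)
        assert list(table.columns) == TRAIT_COLUMNS
        assert table.notna().all().all()

    def test_zero_marbling_phantom(self, small_cfg):
        from dataclasses import replace

        cfg = replace(
            small_cfg,
            muscles=tuple(
                replace(m, marbling=MarblingSpec(particles_per_cm2=0.0))
                for m in small_cfg.muscles
            ),
        )
        row = extract_iat_table([generate_phantom(cfg, seed=0)]).iloc[0]
        for col in TRAIT_COLUMNS:
            low = col.lower()
            if "marbling" in low or "fineness" in low or "coarseness" in low:
                assert row[col] == 0.0

    def test_missing_label_yields_nan_row_retained(self, small_phantom):
        labels = small_phantom.label_map.copy()
        labels[labels == 2] = 8  # drop M. semispinalis capitis
        table = extract_iat_table(
            [(small_phantom.image, labels, small_phantom.target_polygon_px, small_phantom.px_per_cm)]
        )
        assert len(table) == 1
        assert table["M. semispinalis capitis: Area (cm2)"].isna().all()
        assert table["M. longissimus dorsi: Area (cm2)"].notna().all()

    def test_marbling_plus_lean_is_total(self, small_phantom):
        row = extract_iat_table([small_phantom]).iloc[0]
        # noiseless phantom: marbling% + lean% must be exactly 100
        mask = small_phantom.label_map == 1
        marb = small_phantom.marbling_mask & mask
        lean_pct = 100.0 * (mask.sum() - marb.sum()) / mask.sum()
        assert row["M. longissimus dorsi: Marbling percentage (%)"] + lean_pct == pytest.approx(100.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    st.lists(
        st.tuples(st.floats(0.01, 2.0), st.floats(0.4, 10.0)),
        max_size=30,
    )
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_marbling_index_invariants(parts):
    """Coarseness never exceeds marbling percentage; indices are bounded."""
    particles = [MarblingParticle(10, a, p) for a, p in parts]
    muscle_area = sum(a for a, _ in parts) + 50.0
    idx = marbling_indices(particles, muscle_area)
    assert 0.0 <= idx.coarseness_index <= idx.marbling_percentage <= 100.0
    assert idx.new_fineness_index >= 0.0


@given(st.integers(3, 15), st.integers(16, 40), st.integers(0, 5), st.integers(0, 5))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_rectangle_thickness_is_short_side(h, w, r0, c0):
    """Axis-aligned rectangles: thickness equals the short side exactly."""
    mask = np.zeros((60, 60), dtype=bool)
    mask[r0:r0 + h, c0:c0 + w] = True
    geom = region_geometry(mask, 10.0)
    assert geom.thickness_mm == pytest.approx(h, abs=1e-9)
    assert geom.area_cm2 == pytest.approx(h * w / 100.0)
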