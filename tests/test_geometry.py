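"""Measurement-region construction: offset bands, compartment overlay, areas."""

import math

import numpy as np
import pytest
import shapely
from shapely import affinity
from shapely.geometry import MultiPolygon, Point, Polygon, box

from tilquant.geometry import (
    BACKGROUND,
    EPITHELIUM,
    STROMA,
    GeometryError,
    TissueCase,
    area_mm2,
    build_margin_band,
    build_regions,
    overlay_compartments,
)

from .conftest import random_star_polygon, segment_distance


class TestMarginBand:
    def test_annulus_closed_form(self):
        """Band around a 2 mm disk with 500 um half-width is a 4*pi mm^2 annulus."""
        disk = Point(0, 0).buffer(2000, quad_segs=128)
        band = build_margin_band(disk, 500)
        assert band.area_mm2 == pytest.approx(math.pi * (2.5**2 - 1.5**2), rel=1e-3)
        assert band.inner_area_mm2 == pytest.approx(math.pi * (2.0**2 - 1.5**2), rel=1e-3)
        assert band.outer_area_mm2 == pytest.approx(math.pi * (2.5**2 - 2.0**2), rel=1e-3)

    @pytest.mark.parametrize("half_width_um,expected_mm", [(500, 1.0), (1000, 2.0)])
    def test_straight_boundary_effective_width(self, half_width_um, expected_mm):
        """Dilating a straight boundary both ways yields the stated total band width."""
        bulk = box(0, 0, 20000, 10000)  # straight edge at y=10000, far from corners
        band = build_margin_band(bulk, half_width_um)
        # perpendicular transect through the top edge, starting mid-bulk so it
        # meets only this edge's band
        transect = shapely.LineString([(10000, 5000), (10000, 30000)])
        width_mm = band.band.intersection(transect).length / 1000.0
        assert width_mm == pytest.approx(expected_mm, abs=1e-9)

    def test_erosion_annihilation_flagged_not_error(self):
        """A tumour thinner than twice the half-width keeps the whole bulk as inner."""
        sliver = box(0, 0, 10000, 600)  # 0.6 mm thick
        band = build_margin_band(sliver, 500)
        assert band.inner_is_whole_bulk
        assert band.inner_area_mm2 == pytest.approx(area_mm2(sliver))

    def test_invalid_inputs_rejected(self):
        bowtie = Polygon([(0, 0), (1000, 1000), (1000, 0), (0, 1000)])
        with pytest.raises(GeometryError):
            build_margin_band(bowtie, 500)
        with pytest.raises(GeometryError):
            build_margin_band(box(0, 0, 1000, 1000), -5)

    def test_outer_clipped_to_tissue_extent(self):
        bulk = box(0, 0, 4000, 4000)
        extent = box(-500, -500, 4500, 4500)  # only 500 um of tissue around
        band = build_margin_band(bulk, 1000, tissue_extent=extent)
        full = build_margin_band(bulk, 1000)
        assert band.outer_area_mm2 < full.outer_area_mm2
        assert band.outer.difference(extent).area == pytest.approx(0.0, abs=1e-6)

    def test_multifocal_bands_counted_once(self):
        """Overlapping bands of two nearby foci are unioned, not double counted."""
        a = Point(0, 0).buffer(1000, quad_segs=64)
        b = Point(2600, 0).buffer(1000, quad_segs=64)  # outer bands overlap
        band = build_margin_band(MultiPolygon([a, b]), 500)
        separate = (
            build_margin_band(a, 500).band.union(build_margin_band(b, 500).band)
        )
        assert band.band.area == pytest.approx(separate.area, rel=1e-6)

    def test_band_matches_distance_oracle(self):
        """Offset-band membership agrees with brute-force distance classification."""
        rng = np.random.default_rng(7)
        h = 500.0
        for _ in range(3):
            poly = random_star_polygon(rng)
            band = build_margin_band(poly, h)
            minx, miny, maxx, maxy = band.dilated.bounds
            xs = np.arange(minx, maxx, 10.0)
            ys = np.arange(miny, maxy, 10.0)
            gx, gy = np.meshgrid(xs, ys)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            d = segment_distance(pts, np.asarray(poly.exterior.coords))
            oracle = d <= h
            ours = shapely.intersects_xy(band.band, pts[:, 0], pts[:, 1])
            assert (oracle == ours).mean() >= 0.995
            # disagreements confined to within one grid pitch of the band edge
            disagree = d[oracle != ours]
            if disagree.size:
                assert np.all(np.abs(disagree - h) <= 10.0)

    def test_im1_nested_in_im2(self, default_case):
        case, _, regions = default_case
        assert regions.im1.inner.difference(regions.im2.inner).area < 1e-3
        assert regions.im1.outer.difference(regions.im2.outer).area < 1e-3


class TestCompartmentOverlay:
    def _square_case(self, mask, res=100.0, side_um=2000.0):
        return TissueCase(
            case_id="sq", bulk=box(0, 0, side_um, side_um),
            tissue_extent=box(-1000, -1000, side_um + 1000, side_um + 1000),
            compartment_mask=mask, resolution_um_per_px=res,
        )

    def test_all_epithelium_degenerate_partition(self):
        mask = np.full((20, 20), EPITHELIUM, dtype=np.uint8)
        ov = overlay_compartments(self._square_case(mask))
        assert ov.its_area_mm2 == 0.0
        assert ov.itt_area_mm2 == pytest.approx(ov.ita_area_mm2)

    def test_checkerboard_symmetry(self):
        mask = np.indices((20, 20)).sum(axis=0) % 2
        mask = np.where(mask, EPITHELIUM, STROMA).astype(np.uint8)
        ov = overlay_compartments(self._square_case(mask))
        px = (100.0 / 1000.0) ** 2
        assert abs(ov.itt_area_mm2 - 2.0) <= 20 * px  # one pixel row
        assert abs(ov.its_area_mm2 - 2.0) <= 20 * px

    def test_blob_fraction_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(3)
        noise = rng.standard_normal((40, 40))
        from scipy.ndimage import gaussian_filter

        blob = gaussian_filter(noise, 4) > 0
        mask = np.where(blob, EPITHELIUM, STROMA).astype(np.uint8)
        ov = overlay_compartments(self._square_case(mask, res=50.0))
        frac_pixels = (mask[ov.inside_bulk] == EPITHELIUM).mean()
        assert ov.itt_area_mm2 / ov.ita_area_mm2 == pytest.approx(frac_pixels, abs=1e-4)

    def test_partition_is_exact_and_exclusive(self, default_case):
        case, _, regions = default_case
        ov = regions.overlay
        assert ov.ita_area_mm2 == pytest.approx(ov.itt_area_mm2 + ov.its_area_mm2, abs=1e-12)
        assert not np.any(ov.itt_mask & ov.its_mask)
        assert np.array_equal(ov.itt_mask | ov.its_mask, ov.inside_bulk)

    def test_frame_mismatch_rejected(self):
        mask = np.full((3, 3), STROMA, dtype=np.uint8)  # far too small for 2 mm bulk
        with pytest.raises(GeometryError, match="cover"):
            overlay_compartments(self._square_case(mask, res=100.0))

    def test_extra_labels_rejected(self):
        mask = np.full((20, 20), 7, dtype=np.uint8)
        with pytest.raises(GeometryError, match="merge"):
            overlay_compartments(self._square_case(mask))


class TestArea:
    def test_unit_square_and_empty(self):
        assert area_mm2(box(0, 0, 1000, 1000)) == pytest.approx(1.0)
        assert area_mm2(Polygon()) == 0.0

    def test_raster_disk_one_mm2(self):
        """A rasterized disk of radius sqrt(1/pi) mm covers 1 mm^2 within 0.5%."""
        res = 2.0
        r = math.sqrt(1 / math.pi) * 1000.0  # 564.19 um
        n = int(2 * r / res) + 4
        yy, xx = np.indices((n, n))
        cx = cy = n / 2
        disk = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= (r / res) ** 2
        assert area_mm2(disk, res) == pytest.approx(1.0, rel=0.005)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_scale_covariance(self, scale):
        """Scaling all coordinates by s scales every band area by s^2."""
        rng = np.random.default_rng(11)
        poly = random_star_polygon(rng)
        base = build_margin_band(poly, 500)
        scaled = build_margin_band(affinity.scale(poly, scale, scale, origin=(0, 0)),
                                   500 * scale)
        assert scaled.inner_area_mm2 == pytest.approx(base.inner_area_mm2 * scale**2, rel=1e-6)
        assert scaled.outer_area_mm2 == pytest.approx(base.outer_area_mm2 * scale**2, rel=1e-6)


def test_build_regions_area_table(default_case):
    case, _, regions = default_case
    areas = regions.region_areas()
    assert set(areas) == {"ITA", "ITT", "ITS", "IM1", "IM2",
                          "IM1_inner", "IM1_outer", "IM2_inner", "IM2_outer"}
    assert all(v >= 0 for v in areas.values())
    assert areas["IM1"] == pytest.approx(areas["IM1_inner"] + areas["IM1_outer"])
    # rasterized ITA area within boundary-quantisation tolerance of polygon area
    perim_um = regions.bulk.length
    tol = perim_um * case.resolution_um_per_px / 1e6 * 1.5
    assert abs(regions.ita_area_mm2 - regions.bulk_area_mm2_polygon) <= tol
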