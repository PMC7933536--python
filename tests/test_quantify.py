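"""Per-case measures: counting, densities, ratios, heatmaps, conservation."""

import math

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Polygon, box

from tilquant.geometry import TissueCase, build_regions
from tilquant.quantify import (
    DetectionSet,
    QuantifyError,
    count_in_region,
    density_heatmap,
    density_per_mm2,
    inner_outer_ratio,
    marker_ratio,
    measure_case,
    measure_columns,
    scaled_covariate,
    window_radius_um,
)
from tilquant.simulate import SimConfig, generate_case

from .conftest import random_star_polygon


def crossing_number_inside(pts: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force even-odd point-in-polygon test (ray to +x)."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(coords) - 1
    for i in range(n):
        x1, y1 = coords[i]
        x2, y2 = coords[i + 1]
        crosses = ((y1 > y) != (y2 > y)) & (x < (x2 - x1) * (y - y1) / (y2 - y1) + x1)
        inside ^= crosses
    return inside


class TestCounting:
    def test_simple_counts(self):
        sq = box(0, 0, 1000, 1000)
        pts = np.array([[100, 100], [500, 500], [900, 900], [2000, 0], [-1, -1]], float)
        assert count_in_region(pts, sq) == 3

    def test_boundary_point_counts_inner_side(self):
        """A detection exactly on the bulk outline belongs to the tumour side."""
        cfg = SimConfig(n_cases=1, seed=5, radius_mm_mean=1.2, radius_mm_sd=0.1)
        case, detections = generate_case(cfg, 0)
        regions = build_regions(case)
        edge_pt = np.asarray(case.bulk.geoms[0].exterior.coords)[0]
        dets = {
            m: DetectionSet(case.case_id, m, np.array([edge_pt]))
            for m in ("CD3", "CD8", "FOXP3")
        }
        row = measure_case(regions, dets)
        assert row["CD3_ITA_count"] == 1
        n_in, n_out = 1, 0
        assert row["CD3_IM1_count"] == n_in + n_out  # counted in the inner half only

    def test_matches_crossing_number_oracle(self):
        rng = np.random.default_rng(17)
        poly = random_star_polygon(rng)
        minx, miny, maxx, maxy = poly.bounds
        pts = np.column_stack([
            rng.uniform(minx - 200, maxx + 200, 10_000),
            rng.uniform(miny - 200, maxy + 200, 10_000),
        ])
        oracle = crossing_number_inside(pts, np.asarray(poly.exterior.coords))
        assert count_in_region(pts, poly) == int(oracle.sum())

    def test_case_mismatch_rejected(self, default_case):
        _, _, regions = default_case
        dets = {m: DetectionSet("other", m, np.empty((0, 2))) for m in ("CD3", "CD8", "FOXP3")}
        with pytest.raises(QuantifyError, match="mismatch"):
            measure_case(regions, dets)


class TestScalars:
    def test_density(self):
        assert density_per_mm2(250, 2.5) == 100.0
        assert density_per_mm2(0, 3.0) == 0.0
        assert math.isnan(density_per_mm2(5, 0.0))

    @pytest.mark.parametrize("marker,density,expected", [
        ("CD3", 250.0, 2.5), ("CD8", 250.0, 2.5), ("FOXP3", 25.0, 2.5),
        ("CD3", 0.0, 0.0),
    ])
    def test_scaled_covariate_increments(self, marker, density, expected):
        assert scaled_covariate(density, marker) == expected

    def test_scaled_covariate_unknown_marker(self):
        with pytest.raises(QuantifyError):
            scaled_covariate(10.0, "CD20")

    def test_inner_outer_ratio(self):
        assert inner_outer_ratio(50.0, 25.0) == 2.0
        assert inner_outer_ratio(33.0, 33.0) == 1.0
        assert math.isnan(inner_outer_ratio(10.0, 0.0))
        with pytest.raises(QuantifyError):
            inner_outer_ratio(-1.0, 5.0)

    def test_marker_ratio(self):
        assert marker_ratio(40, 80) == 0.5
        assert marker_ratio(7, 7) == 1.0
        assert math.isnan(marker_ratio(3, 0))
        with pytest.raises(QuantifyError):
            marker_ratio(-1, 2)


class TestCaseMeasures:
    def test_count_conservation(self, default_case):
        """ITA count = ITT + ITS count exactly, for every marker."""
        case, detections, regions = default_case
        row = measure_case(regions, detections)
        for m in ("CD3", "CD8", "FOXP3"):
            assert row[f"{m}_ITA_count"] == row[f"{m}_ITT_count"] + row[f"{m}_ITS_count"]
            assert row[f"{m}_ITA"] == pytest.approx(
                row[f"{m}_ITA_density"] / (100 if m != "FOXP3" else 10)
            )

    def test_translation_invariance(self):
        """Shifting geometry and detections together changes no measure."""
        cfg = SimConfig(n_cases=1, seed=9, radius_mm_mean=1.2, radius_mm_sd=0.1)
        case, detections = generate_case(cfg, 0)
        row0 = measure_case(build_regions(case), detections)

        dx, dy = 12_345.0, -6_789.0
        shifted_case = TissueCase(
            case_id=case.case_id,
            bulk=affinity.translate(case.bulk, dx, dy),
            tissue_extent=affinity.translate(case.tissue_extent, dx, dy),
            compartment_mask=case.compartment_mask,
            resolution_um_per_px=case.resolution_um_per_px,
            mask_origin_um=(case.mask_origin_um[0] + dx, case.mask_origin_um[1] + dy),
        )
        shifted_dets = {
            m: DetectionSet(case.case_id, m, d.points + [dx, dy])
            for m, d in detections.items()
        }
        row1 = measure_case(build_regions(shifted_case), shifted_dets)
        for key in row0:
            if key == "case_id":
                continue
            assert row1[key] == pytest.approx(row0[key], rel=1e-9, nan_ok=True), key

    def test_adding_point_never_decreases_density(self, default_case):
        case, detections, regions = default_case
        row0 = measure_case(regions, detections)
        centroid = np.asarray(case.bulk.centroid.coords)[0]
        boosted = dict(detections)
        boosted["CD3"] = DetectionSet(
            case.case_id, "CD3", np.vstack([detections["CD3"].points, centroid])
        )
        row1 = measure_case(regions, boosted)
        assert row1["CD3_ITA_density"] > row0["CD3_ITA_density"]
        assert row1["CD3_ITA_count"] == row0["CD3_ITA_count"] + 1

    def test_measure_columns_cover_reported_rows(self):
        cols = measure_columns()
        for m in ("CD3", "CD8", "FOXP3"):
            for r in ("ITA", "ITT", "ITS", "IM1", "IM2", "IM1IO", "IM2IO"):
                assert f"{m}_{r}" in cols
        assert "CD8_CD3_ratio_ITA" in cols and "CD8_FOXP3_ratio_IM2IO" in cols


class TestHeatmap:
    def test_window_radius_for_unit_area(self):
        assert window_radius_um(1.0) == pytest.approx(564.19, abs=0.01)

    def test_empty_detections_all_zero(self):
        grid, xs, ys = density_heatmap(np.empty((0, 2)), box(0, 0, 3000, 3000))
        assert grid.shape == (len(ys), len(xs))
        assert np.all(grid == 0.0)

    def test_homogeneous_poisson_mean_recovery(self):
        lam = 50.0  # cells/mm^2
        frame = box(0, 0, 10_000, 10_000)
        rng = np.random.default_rng(23)
        n = rng.poisson(lam * 100.0)
        pts = rng.uniform(0, 10_000, (n, 2))
        grid, _, _ = density_heatmap(pts, frame, stride_um=500.0)
        se = math.sqrt(lam * 100.0) / 100.0
        assert abs(grid.mean() - lam) <= 3 * se
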