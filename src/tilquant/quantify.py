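"""Per-case TIL measures: counts, densities, scaled covariates and ratios.

For each marker (CD3, CD8, FOXP3) and each measurement region the module
computes the cell count, the density in cells/mm^2 and the scaled covariate
used by the survival models (density per increment of 100 cells for CD3/CD8,
per 10 for FOXP3), plus the inner/outer invasive-margin density ratios
(IM1IO, IM2IO) and between-marker count ratios.  Undefined quantities (zero
denominator, zero area) are carried as NaN and excluded case-wise downstream.

Boundary tie rule: a detection exactly on the bulk outline belongs to the
tumour side (inner); inside the bulk a detection takes the compartment of the
pixel containing it, background pixels deferring to the nearest labelled
pixel.  Every detection in the bulk therefore lands in exactly one of ITT/ITS
and counts are exactly conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .geometry import EPITHELIUM, STROMA, GeometryError, MarginBand, RegionSet

MARKERS = ("CD3", "CD8", "FOXP3")

#: Covariate scaling: cells per increment, per marker.
INCREMENTS = {"CD3": 100.0, "CD8": 100.0, "FOXP3": 10.0}

#: Ordered (numerator, denominator) marker pairs for the count ratios.
MARKER_PAIRS = (("CD8", "CD3"), ("FOXP3", "CD3"), ("CD8", "FOXP3"))

#: Regions over which plain densities/counts are reported.
DENSITY_REGIONS = ("ITA", "ITT", "ITS", "IM1", "IM2")


class QuantifyError(ValueError):
    """Raised on contract violations in measure computation."""


@dataclass
class DetectionSet:
    """Marker-labelled point detections for one case, micrometre coordinates."""

    case_id: str
    marker: str
    points: np.ndarray  # (n, 2) float array of (x_um, y_um)
    transform: np.ndarray | None = None  # optional 2x3 affine, applied on creation

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise QuantifyError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.isfinite(pts).all():
            raise QuantifyError(f"case {self.case_id}: non-finite detection coordinates")
        if self.transform is not None:
            t = np.asarray(self.transform, dtype=float)
            if t.shape != (2, 3):
                raise QuantifyError("affine transform must be 2x3")
            pts = pts @ t[:, :2].T + t[:, 2]
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


def count_in_region(points: DetectionSet | np.ndarray, region: BaseGeometry) -> int:
    """Number of points inside or on the boundary of a vector region."""
    pts = points.points if isinstance(points, DetectionSet) else np.asarray(points, float)
    if len(pts) == 0 or region.is_empty:
        return 0
    return int(np.count_nonzero(shapely.intersects_xy(region, pts[:, 0], pts[:, 1])))


def density_per_mm2(count: int, area_mm2: float) -> float:
    """Density in cells/mm^2; NaN (undefined) when the region has zero area."""
    if count < 0:
        raise QuantifyError("negative count")
    if not area_mm2 > 0:
        return float("nan")
    return count / area_mm2


def scaled_covariate(density: float, marker: str) -> float:
    """Density expressed per increment (100 cells for CD3/CD8, 10 for FOXP3)."""
    if marker not in INCREMENTS:
        raise QuantifyError(f"unknown marker {marker!r}")
    if density < 0:
        raise QuantifyError("negative density")
    return density / INCREMENTS[marker]


def inner_outer_ratio(inner_density: float, outer_density: float) -> float:
    """Inner/outer band density ratio; NaN when the outer density is 0 or undefined."""
    if inner_density < 0 or outer_density < 0:
        raise QuantifyError("negative density")
    if not outer_density > 0 or np.isnan(inner_density):
        return float("nan")
    return inner_density / outer_density


def marker_ratio(count_a: int, count_b: int) -> float:
    """Ratio of absolute counts between two markers; NaN when count_b == 0."""
    if count_a < 0 or count_b < 0:
        raise QuantifyError("negative count")
    if count_b == 0:
        return float("nan")
    return count_a / count_b


def _band_counts(pts: np.ndarray, bulk: BaseGeometry, band: MarginBand,
                 extent: BaseGeometry, in_bulk: np.ndarray) -> tuple[int, int]:
    """Inner/outer counts for one margin band with the inner-side tie rule.

    Inner: in the bulk (boundary included) and not strictly interior to the
    eroded core. Outer: within the dilation and tissue frame but not in the
    bulk — points exactly on the bulk outline thus count as inner.
    """
    if len(pts) == 0:
        return 0, 0
    x, y = pts[:, 0], pts[:, 1]
    if band.inner_is_whole_bulk or band.eroded.is_empty:
        in_core = np.zeros(len(pts), dtype=bool)
    else:
        in_core = shapely.contains_xy(band.eroded, x, y)
    inner = in_bulk & ~in_core
    in_dilated = shapely.intersects_xy(band.dilated, x, y)
    in_extent = shapely.intersects_xy(extent, x, y)
    outer = in_dilated & in_extent & ~in_bulk
    return int(inner.sum()), int(outer.sum())


def _compartment_counts(pts: np.ndarray, regions: RegionSet, in_bulk: np.ndarray) -> tuple[int, int]:
    """ITT/ITS counts: each in-bulk point takes its (EDT-filled) pixel's label."""
    ov = regions.overlay
    if ov is None:
        raise QuantifyError(f"case {regions.case_id}: compartment counts need a mask overlay")
    if not in_bulk.any():
        return 0, 0
    res = ov.resolution_um_per_px
    x0, y0 = ov.origin_um
    sub = pts[in_bulk]
    cols = np.clip(((sub[:, 0] - x0) / res).astype(int), 0, ov.filled_labels.shape[1] - 1)
    rows = np.clip(((sub[:, 1] - y0) / res).astype(int), 0, ov.filled_labels.shape[0] - 1)
    labels = ov.filled_labels[rows, cols]
    n_itt = int(np.count_nonzero(labels == EPITHELIUM))
    n_its = int(np.count_nonzero(labels == STROMA))
    return n_itt, n_its


@dataclass
class MarkerMeasures:
    """All region measures for one marker on one case."""

    marker: str
    counts: dict[str, int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)
    covariates: dict[str, float] = field(default_factory=dict)
    im1io: float = float("nan")
    im2io: float = float("nan")
    inner_outer_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def measure_marker(detections: DetectionSet, regions: RegionSet) -> MarkerMeasures:
    """Counts, densities and covariates for one marker over all regions."""
    if detections.case_id != regions.case_id:
        raise QuantifyError(
            f"case mismatch: detections {detections.case_id!r} vs regions {regions.case_id!r}"
        )
    pts = detections.points
    if len(pts):
        in_bulk = shapely.intersects_xy(regions.bulk, pts[:, 0], pts[:, 1])
    else:
        in_bulk = np.zeros(0, dtype=bool)

    m = MarkerMeasures(marker=detections.marker)
    n_ita = int(in_bulk.sum())
    if regions.overlay is not None:
        n_itt, n_its = _compartment_counts(pts, regions, in_bulk)
    else:
        n_itt = n_its = 0
    io_counts = {}
    for name, band in (("IM1", regions.im1), ("IM2", regions.im2)):
        n_in, n_out = _band_counts(pts, regions.bulk, band, regions.tissue_extent, in_bulk)
        io_counts[name] = (n_in, n_out)

    m.counts = {
        "ITA": n_ita, "ITT": n_itt, "ITS": n_its,
        "IM1": sum(io_counts["IM1"]), "IM2": sum(io_counts["IM2"]),
    }
    m.inner_outer_counts = io_counts
    areas = regions.region_areas()
    m.densities = {r: density_per_mm2(m.counts[r], areas[r]) for r in DENSITY_REGIONS}
    m.covariates = {
        r: (scaled_covariate(d, m.marker) if not np.isnan(d) else float("nan"))
        for r, d in m.densities.items()
    }
    for name, attr in (("IM1", "im1io"), ("IM2", "im2io")):
        n_in, n_out = io_counts[name]
        band = regions.im1 if name == "IM1" else regions.im2
        d_in = density_per_mm2(n_in, band.inner_area_mm2)
        d_out = density_per_mm2(n_out, band.outer_area_mm2)
        ratio = float("nan") if np.isnan(d_in) or np.isnan(d_out) else inner_outer_ratio(d_in, d_out)
        setattr(m, attr, ratio)
    return m


def measure_case(regions: RegionSet, detections: dict[str, DetectionSet]) -> dict[str, float]:
    """One measures-table row for a case.

    Columns follow the reporting convention ``<marker>_<region>`` for the
    scaled covariates (the quantities the survival models consume),
    ``<marker>_IM1IO`` / ``<marker>_IM2IO`` for the inner/outer ratios, and
    ``<a>_<b>_ratio_<region>`` for between-marker count ratios; raw counts,
    densities and areas are carried with explicit suffixes.
    """
    row: dict[str, float] = {"case_id": regions.case_id}
    per_marker: dict[str, MarkerMeasures] = {}
    for marker in MARKERS:
        if marker not in detections:
            raise QuantifyError(f"case {regions.case_id}: missing detections for {marker}")
        per_marker[marker] = measure_marker(detections[marker], regions)

    for r, a in regions.region_areas().items():
        row[f"area_{r}_mm2"] = a
    for marker, m in per_marker.items():
        for r in DENSITY_REGIONS:
            row[f"{marker}_{r}_count"] = m.counts[r]
            row[f"{marker}_{r}_density"] = m.densities[r]
            row[f"{marker}_{r}"] = m.covariates[r]
        row[f"{marker}_IM1IO"] = m.im1io
        row[f"{marker}_IM2IO"] = m.im2io
    for a, b in MARKER_PAIRS:
        for r in DENSITY_REGIONS:
            row[f"{a}_{b}_ratio_{r}"] = marker_ratio(
                per_marker[a].counts[r], per_marker[b].counts[r]
            )
        # Inner/outer cross-ratios: ratio of the two markers' IO ratios
        # (area factors cancel, so this is a pure count cross-ratio).
        for io in ("IM1IO", "IM2IO"):
            num = getattr(per_marker[a], io.lower())
            den = getattr(per_marker[b], io.lower())
            row[f"{a}_{b}_ratio_{io}"] = num / den if den and not np.isnan(den) and den > 0 and not np.isnan(num) else float("nan")
    return row


def measures_table(rows: list[dict[str, float]]) -> pd.DataFrame:
    """Assemble per-case rows into the cohort measures table."""
    df = pd.DataFrame(rows)
    return df.set_index("case_id") if "case_id" in df else df


#: Measure column names, in reporting order, for the survival analyses.
def measure_columns() -> list[str]:
    cols = []
    for marker in MARKERS:
        cols += [f"{marker}_{r}" for r in DENSITY_REGIONS] + [f"{marker}_IM1IO", f"{marker}_IM2IO"]
    for a, b in MARKER_PAIRS:
        cols += [f"{a}_{b}_ratio_{r}" for r in DENSITY_REGIONS]
        cols += [f"{a}_{b}_ratio_IM1IO", f"{a}_{b}_ratio_IM2IO"]
    return cols


def window_radius_um(window_area_mm2: float) -> float:
    """Radius (um) of a circular window of the given area (mm^2)."""
    if window_area_mm2 <= 0:
        raise QuantifyError("window_area_mm2 must be positive")
    return float(np.sqrt(window_area_mm2 / np.pi) * 1000.0)


def density_heatmap(
    points: DetectionSet | np.ndarray,
    frame: BaseGeometry,
    window_area_mm2: float = 1.0,
    stride_um: float = 250.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window density map over the tissue frame.

    At each grid node the detections within a circular window of
    ``window_area_mm2`` (radius ~564.19 um for 1 mm^2) are counted and divided
    by the window area; windows overhanging the frame use the clipped disk
    area instead, so edge densities stay unbiased.

    Returns ``(grid, x_nodes_um, y_nodes_um)`` with grid shape
    ``(len(y_nodes), len(x_nodes))`` in cells/mm^2.
    """
    from scipy.spatial import cKDTree

    if stride_um <= 0:
        raise QuantifyError("stride_um must be positive")
    pts = points.points if isinstance(points, DetectionSet) else np.asarray(points, float).reshape(-1, 2)
    r_um = window_radius_um(window_area_mm2)
    minx, miny, maxx, maxy = frame.bounds
    xs = np.arange(minx, maxx + stride_um / 2, stride_um)
    ys = np.arange(miny, maxy + stride_um / 2, stride_um)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    if len(pts):
        counts = cKDTree(pts).query_ball_point(nodes, r_um, return_length=True).astype(float)
    else:
        counts = np.zeros(len(nodes))

    # Clipped window areas: only nodes whose disk can overhang the frame need
    # exact polygon clipping.
    areas = np.full(len(nodes), window_area_mm2)
    near_edge = (
        (nodes[:, 0] - minx < r_um) | (maxx - nodes[:, 0] < r_um)
        | (nodes[:, 1] - miny < r_um) | (maxy - nodes[:, 1] < r_um)
    )
    if near_edge.any():
        import shapely.geometry as sgeom

        for i in np.flatnonzero(near_edge):
            disk = sgeom.Point(nodes[i]).buffer(r_um, quad_segs=64)
            areas[i] = disk.intersection(frame).area / 1e6
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(areas > 0, counts / areas, 0.0)
    return grid.reshape(gy.shape), xs, ys
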