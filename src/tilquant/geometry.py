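"""Measurement-region construction for region-based TIL assessment.

A tumour bulk outline (polygons in micrometre slide coordinates) and an
epithelium/stroma label raster are turned into the seven measurement
geometries used throughout the package:

* ``ITA`` — the intratumoural area, i.e. the whole bulk;
* ``ITT`` / ``ITS`` — the epithelial and stromal pixel subsets of the bulk;
* ``IM1`` / ``IM2`` — invasive-margin bands obtained by offsetting the bulk
  outline to both sides by 500 um and 1 mm respectively (total band widths of
  1 mm and 2 mm), each split into an inner (tumour-side) and outer
  (peritumoural) half.

Conventions, used everywhere in the package: coordinates are micrometres,
origin at the top-left of the slide, y increasing downward; polygons follow
the even-odd fill rule; rasters are sampled at pixel centres with 0-based
row/column indices and half-open pixel extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.base import BaseGeometry

# Compartment-mask labels.
BACKGROUND = 0
EPITHELIUM = 1
STROMA = 2

#: Native spatial resolution of the H&E scans the method was designed around,
#: in micrometres per pixel.  Synthetic rasters typically use a much coarser
#: grid; this constant is only a default for real-data manifests.
NATIVE_RESOLUTION_UM_PER_PX = 0.12

#: Offset half-widths (um) defining the IM1 and IM2 invasive-margin bands.
IM1_HALF_WIDTH_UM = 500.0
IM2_HALF_WIDTH_UM = 1000.0

# Segments per quarter circle for round buffer joins; high enough that the
# offset band deviates from the true Euclidean offset by far less than a
# micrometre at the half-widths used here.
_QUAD_SEGS = 32


class GeometryError(ValueError):
    """Raised when an input geometry violates the module's contracts."""


def _as_multipolygon(geom: BaseGeometry) -> MultiPolygon:
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    raise GeometryError(f"expected Polygon or MultiPolygon, got {geom.geom_type}")


def validate_bulk(bulk: BaseGeometry) -> MultiPolygon:
    """Check that a bulk annotation is a valid, simple, positive-area polygon set."""
    mp = _as_multipolygon(bulk)
    if not mp.is_valid:
        raise GeometryError(f"bulk polygon set is invalid: {shapely.is_valid_reason(mp)}")
    if mp.area <= 0:
        raise GeometryError("bulk polygon set has zero area")
    return mp


@dataclass
class TissueCase:
    """Geometry bundle for one tumour: outline, tissue frame and compartment raster.

    Parameters
    ----------
    case_id:
        Opaque case identifier.
    bulk:
        Tumour-bulk outline(s), micrometre coordinates. Holes are allowed.
    tissue_extent:
        Polygon bounding the scanned tissue; the outer margin halves are
        clipped to it.
    compartment_mask:
        2-D ``uint8`` label grid over the bulk's bounding box with labels
        ``{BACKGROUND, EPITHELIUM, STROMA}``. May be ``None`` for cases where
        only margin measures are needed.
    resolution_um_per_px:
        Micrometres per pixel of ``compartment_mask``.
    mask_origin_um:
        Slide coordinates ``(x, y)`` of the mask's top-left pixel corner.
    """

    case_id: str
    bulk: MultiPolygon
    tissue_extent: BaseGeometry
    compartment_mask: np.ndarray | None
    resolution_um_per_px: float
    mask_origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise GeometryError("resolution_um_per_px must be positive")
        self.bulk = validate_bulk(self.bulk)


@dataclass
class MarginBand:
    """Inner/outer halves of one invasive-margin band, with areas in mm^2."""

    half_width_um: float
    inner: BaseGeometry
    outer: BaseGeometry
    inner_area_mm2: float
    outer_area_mm2: float
    #: True when the erosion annihilated the bulk (tumour thinner than twice
    #: the half-width); the inner half then equals the whole bulk.
    inner_is_whole_bulk: bool = False
    #: Interior region left after erosion (bulk minus inner half); needed for
    #: boundary-inclusive point classification.
    eroded: BaseGeometry = field(default_factory=Polygon)
    #: Bulk dilated outward by the half-width, before clipping.
    dilated: BaseGeometry = field(default_factory=Polygon)

    @property
    def band(self) -> BaseGeometry:
        return self.inner.union(self.outer)

    @property
    def area_mm2(self) -> float:
        return self.inner_area_mm2 + self.outer_area_mm2


@dataclass
class CompartmentOverlay:
    """Epithelium/stroma subdivision of the bulk on the mask raster."""

    inside_bulk: np.ndarray  # bool, pixel centre inside the bulk
    itt_mask: np.ndarray  # bool, inside bulk and epithelium
    its_mask: np.ndarray  # bool, inside bulk and stroma
    filled_labels: np.ndarray  # every pixel assigned its nearest non-background label
    resolution_um_per_px: float
    origin_um: tuple[float, float]
    ita_area_mm2: float
    itt_area_mm2: float
    its_area_mm2: float


@dataclass
class RegionSet:
    """All measurement geometries for one case, with areas in mm^2."""

    case_id: str
    bulk: MultiPolygon
    tissue_extent: BaseGeometry
    ita_area_mm2: float  # rasterized bulk area; exact partition with ITT+ITS
    bulk_area_mm2_polygon: float  # exact polygon area, for reference
    overlay: CompartmentOverlay | None
    im1: MarginBand
    im2: MarginBand

    @property
    def itt_area_mm2(self) -> float:
        return self.overlay.itt_area_mm2 if self.overlay is not None else float("nan")

    @property
    def its_area_mm2(self) -> float:
        return self.overlay.its_area_mm2 if self.overlay is not None else float("nan")

    def region_areas(self) -> dict[str, float]:
        return {
            "ITA": self.ita_area_mm2,
            "ITT": self.itt_area_mm2,
            "ITS": self.its_area_mm2,
            "IM1": self.im1.area_mm2,
            "IM2": self.im2.area_mm2,
            "IM1_inner": self.im1.inner_area_mm2,
            "IM1_outer": self.im1.outer_area_mm2,
            "IM2_inner": self.im2.inner_area_mm2,
            "IM2_outer": self.im2.outer_area_mm2,
        }


def area_mm2(region: BaseGeometry | np.ndarray, resolution_um_per_px: float | None = None) -> float:
    """Area of a region in mm^2.

    Vector geometries use the exact polygon area; boolean rasters use
    ``pixel_count * (resolution_um / 1000)**2`` and require ``resolution_um_per_px``.
    Empty regions have area 0.
    """
    if isinstance(region, np.ndarray):
        if resolution_um_per_px is None:
            raise GeometryError("raster areas need resolution_um_per_px")
        return float(np.count_nonzero(region)) * (resolution_um_per_px / 1000.0) ** 2
    if region.is_empty:
        return 0.0
    return float(region.area) / 1e6


def build_margin_band(
    bulk: BaseGeometry,
    half_width_um: float,
    tissue_extent: BaseGeometry | None = None,
) -> MarginBand:
    """Build one invasive-margin band by offsetting the bulk outline both ways.

    The outline is dilated inward and outward by ``half_width_um`` using round
    joins (Minkowski sum/difference with a disk), so membership in the band is
    equivalent to Euclidean distance-to-outline <= ``half_width_um``. The outer
    half is clipped to ``tissue_extent`` and the clipped area is reported, so
    tumours abutting the section edge keep honest outer densities.

    Multi-focal bulks are offset per component and unioned; overlap between
    components' bands is counted once.
    """
    if half_width_um <= 0:
        raise GeometryError("half_width_um must be positive")
    mp = validate_bulk(bulk)

    eroded = mp.buffer(-half_width_um, quad_segs=_QUAD_SEGS)
    inner_is_whole_bulk = eroded.is_empty
    inner = mp if inner_is_whole_bulk else mp.difference(eroded)

    dilated = mp.buffer(half_width_um, quad_segs=_QUAD_SEGS)
    outer = dilated.difference(mp)
    if tissue_extent is not None:
        outer = outer.intersection(tissue_extent)

    return MarginBand(
        half_width_um=float(half_width_um),
        inner=inner,
        outer=outer,
        inner_area_mm2=area_mm2(inner),
        outer_area_mm2=area_mm2(outer),
        inner_is_whole_bulk=inner_is_whole_bulk,
        eroded=eroded,
        dilated=dilated,
    )


def mask_pixel_centres(
    shape: tuple[int, int], resolution_um_per_px: float, origin_um: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Slide coordinates (x, y) of every pixel centre of a raster, as 2-D arrays."""
    rows, cols = shape
    x = origin_um[0] + (np.arange(cols) + 0.5) * resolution_um_per_px
    y = origin_um[1] + (np.arange(rows) + 0.5) * resolution_um_per_px
    return np.meshgrid(x, y)


def fill_labels_nearest(mask: np.ndarray) -> np.ndarray:
    """Assign every background pixel the label of its nearest labelled pixel.

    Euclidean distance between pixel centres; exact ties are broken
    deterministically by the distance transform's index propagation.
    """
    background = mask == BACKGROUND
    if not background.any():
        return mask
    if background.all():
        raise GeometryError("compartment mask contains no labelled pixels")
    idx = ndimage.distance_transform_edt(background, return_distances=False, return_indices=True)
    return mask[tuple(idx)]


def overlay_compartments(case: TissueCase) -> CompartmentOverlay:
    """Subdivide the bulk into epithelial (ITT) and stromal (ITS) pixel sets.

    A pixel belongs to the bulk when its centre falls strictly inside the bulk
    polygon; the ITA area is the rasterized bulk area so that
    ``area(ITT) + area(ITS) == area(ITA)`` holds exactly.  Labelled pixels keep
    their class; bulk pixels the upstream segmenter left as background (a
    boundary-quantisation artefact) inherit the nearest labelled pixel's class.
    """
    mask = case.compartment_mask
    if mask is None:
        raise GeometryError(f"case {case.case_id}: no compartment mask")
    if mask.ndim != 2:
        raise GeometryError("compartment mask must be 2-D")
    res = case.resolution_um_per_px
    minx, miny, maxx, maxy = case.bulk.bounds
    x0, y0 = case.mask_origin_um
    # Frame check: the mask grid must cover the bulk bounding box.
    if x0 > minx + res or y0 > miny + res:
        raise GeometryError(f"case {case.case_id}: mask origin does not cover the bulk")
    if x0 + mask.shape[1] * res < maxx - res or y0 + mask.shape[0] * res < maxy - res:
        raise GeometryError(f"case {case.case_id}: mask extent does not cover the bulk")
    bad = ~np.isin(mask, (BACKGROUND, EPITHELIUM, STROMA))
    if bad.any():
        raise GeometryError(
            f"case {case.case_id}: mask contains labels outside "
            "{background, epithelium, stroma}; merge extra classes first"
        )

    xs, ys = mask_pixel_centres(mask.shape, res, (x0, y0))
    inside = shapely.contains_xy(case.bulk, xs.ravel(), ys.ravel()).reshape(mask.shape)
    filled = fill_labels_nearest(mask)

    itt = inside & (filled == EPITHELIUM)
    its = inside & (filled == STROMA)
    return CompartmentOverlay(
        inside_bulk=inside,
        itt_mask=itt,
        its_mask=its,
        filled_labels=filled,
        resolution_um_per_px=res,
        origin_um=(x0, y0),
        ita_area_mm2=area_mm2(inside, res),
        itt_area_mm2=area_mm2(itt, res),
        its_area_mm2=area_mm2(its, res),
    )


def build_regions(case: TissueCase) -> RegionSet:
    """Construct the full RegionSet (ITA/ITT/ITS, IM1, IM2) for one case."""
    overlay = overlay_compartments(case) if case.compartment_mask is not None else None
    im1 = build_margin_band(case.bulk, IM1_HALF_WIDTH_UM, case.tissue_extent)
    im2 = build_margin_band(case.bulk, IM2_HALF_WIDTH_UM, case.tissue_extent)
    ita_area = overlay.ita_area_mm2 if overlay is not None else area_mm2(case.bulk)
    return RegionSet(
        case_id=case.case_id,
        bulk=case.bulk,
        tissue_extent=case.tissue_extent,
        ita_area_mm2=ita_area,
        bulk_area_mm2_polygon=area_mm2(case.bulk),
        overlay=overlay,
        im1=im1,
        im2=im2,
    )


def square_extent(bulk: BaseGeometry, margin_um: float = 3000.0) -> Polygon:
    """Axis-aligned tissue frame: the bulk bounding box padded by ``margin_um``."""
    minx, miny, maxx, maxy = bulk.bounds
    return box(minx - margin_um, miny - margin_um, maxx + margin_um, maxy + margin_um)
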