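"""Formats and cohort manifests.

On-disk formats are the plain-text/standard containers practitioners exchange:
GeoJSON for annotations (micrometre coordinates, CRS-less, ``"unit": "um"``),
single-channel TIFF for compartment masks with the resolution in the
manifest, CSV for detections, measures and outcomes, and a YAML manifest
binding a cohort together.  CSV dialect: comma-separated, UTF-8, ``.``
decimal, header row mandatory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .geometry import TissueCase, validate_bulk
from .quantify import MARKERS, DetectionSet

DETECTION_COLUMNS = ["case_id", "marker", "x_um", "y_um"]
OUTCOME_COLUMNS = ["case_id", "rfs_months", "rfs_event", "os_months", "os_event"]


class ManifestError(ValueError):
    pass


# --- annotations -----------------------------------------------------------

def write_bulk_geojson(path: str | Path, case_id: str, bulk) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(bulk),
        "properties": {"case_id": case_id, "unit": "um"},
    }
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))


def read_bulk_geojson(path: str | Path):
    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    if not feats:
        raise ManifestError(f"{path}: no features")
    props = feats[0].get("properties") or {}
    if props.get("unit", "um") != "um":
        raise ManifestError(f"{path}: unsupported unit {props.get('unit')!r}; expected 'um'")
    return validate_bulk(shape(feats[0]["geometry"]))


# --- masks -----------------------------------------------------------------

def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint8))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


# --- detections ------------------------------------------------------------

def write_detections_csv(path: str | Path, detections: dict[str, DetectionSet]) -> None:
    frames = []
    for marker, ds in detections.items():
        frames.append(pd.DataFrame({
            "case_id": ds.case_id, "marker": marker,
            "x_um": ds.points[:, 0], "y_um": ds.points[:, 1],
        }))
    pd.concat(frames, ignore_index=True)[DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections_csv(path: str | Path, case_id: str,
                        transform: np.ndarray | None = None) -> dict[str, DetectionSet]:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing detection columns {sorted(missing)}")
    df = df[df["case_id"].astype(str) == str(case_id)]
    out = {}
    for marker in MARKERS:
        sub = df[df["marker"] == marker]
        out[marker] = DetectionSet(
            case_id=case_id, marker=marker,
            points=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            transform=transform,
        )
    return out


# --- outcomes --------------------------------------------------------------

def write_outcomes_csv(path: str | Path, outcomes: pd.DataFrame) -> None:
    outcomes.reset_index()[OUTCOME_COLUMNS].to_csv(path, index=False)


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OUTCOME_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing outcome columns {sorted(missing)}")
    df["case_id"] = df["case_id"].astype(str)
    return df.set_index("case_id")


# --- manifest --------------------------------------------------------------

@dataclass
class LoadedCase:
    case: TissueCase
    detections: dict[str, DetectionSet]


@dataclass
class CohortLoadResult:
    cases: list[LoadedCase]
    outcomes: pd.DataFrame | None
    errors: list[dict[str, str]] = field(default_factory=list)


def write_manifest(path: str | Path, entries: list[dict], outcomes_path: str | None = None) -> None:
    doc = {"cases": entries}
    if outcomes_path is not None:
        doc["outcomes"] = outcomes_path
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def save_cohort(out_dir: str | Path, cohort, outcomes: pd.DataFrame | None = None) -> Path:
    """Write a simulated cohort in the pipeline's exchange formats.

    Returns the manifest path. Layout: per-case GeoJSON bulk, TIFF mask and
    detections CSV under ``out_dir/cases/``, plus ``outcomes.csv`` and
    ``manifest.yaml``.
    """
    out_dir = Path(out_dir)
    case_dir = out_dir / "cases"
    case_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for case, detections in cohort:
        cid = case.case_id
        write_bulk_geojson(case_dir / f"{cid}_bulk.geojson", cid, case.bulk)
        write_mask_tiff(case_dir / f"{cid}_mask.tif", case.compartment_mask)
        write_detections_csv(case_dir / f"{cid}_detections.csv", detections)
        minx, miny, maxx, maxy = case.tissue_extent.bounds
        entries.append({
            "case_id": cid,
            "bulk": f"cases/{cid}_bulk.geojson",
            "mask": f"cases/{cid}_mask.tif",
            "resolution_um_per_px": float(case.resolution_um_per_px),
            "mask_origin_um": [float(v) for v in case.mask_origin_um],
            "tissue_extent_um": [float(minx), float(miny), float(maxx), float(maxy)],
            "detections": f"cases/{cid}_detections.csv",
        })
    outcomes_rel = None
    if outcomes is not None:
        write_outcomes_csv(out_dir / "outcomes.csv", outcomes)
        outcomes_rel = "outcomes.csv"
    write_manifest(out_dir / "manifest.yaml", entries, outcomes_rel)
    return out_dir / "manifest.yaml"


def load_cohort(manifest_path: str | Path) -> CohortLoadResult:
    """Load and validate a cohort manifest.

    Invalid cases are rejected individually with machine-readable errors; the
    run proceeds on the valid remainder.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    doc = yaml.safe_load(manifest_path.read_text())
    if not doc or "cases" not in doc:
        raise ManifestError(f"{manifest_path}: no 'cases' section")

    from shapely.geometry import box

    seen: set[str] = set()
    cases: list[LoadedCase] = []
    errors: list[dict[str, str]] = []
    for entry in doc["cases"]:
        cid = str(entry.get("case_id", "?"))
        try:
            if cid in seen:
                raise ManifestError(f"duplicate case_id {cid!r}")
            seen.add(cid)
            bulk = read_bulk_geojson(root / entry["bulk"])
            mask = read_mask_tiff(root / entry["mask"]) if entry.get("mask") else None
            res = float(entry["resolution_um_per_px"])
            origin = tuple(entry.get("mask_origin_um", (0.0, 0.0)))
            ext = entry.get("tissue_extent_um")
            extent = box(*ext) if ext else box(*bulk.buffer(3000).bounds)
            transform = None
            if entry.get("transform") is not None:
                transform = np.asarray(entry["transform"], dtype=float).reshape(2, 3)
            case = TissueCase(
                case_id=cid, bulk=bulk, tissue_extent=extent,
                compartment_mask=mask, resolution_um_per_px=res,
                mask_origin_um=origin,
            )
            detections = read_detections_csv(root / entry["detections"], cid, transform)
            cases.append(LoadedCase(case=case, detections=detections))
        except Exception as exc:  # per-case rejection, run continues
            errors.append({"case_id": cid, "error": f"{type(exc).__name__}: {exc}"})

    outcomes = None
    if doc.get("outcomes"):
        outcomes = read_outcomes_csv(root / doc["outcomes"])
    return CohortLoadResult(cases=cases, outcomes=outcomes, errors=errors)
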