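import numpy as np
import pytest
from shapely.geometry import Polygon

from tilquant.geometry import build_regions
from tilquant.simulate import SimConfig, generate_case


@pytest.fixture(scope="session")
def default_case():
    """One modest synthetic tumour shared by read-only tests."""
    cfg = SimConfig(n_cases=1, seed=42, radius_mm_mean=1.5, radius_mm_sd=0.2)
    case, detections = generate_case(cfg, 0)
    return case, detections, build_regions(case)


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 12,
                        r_min_um: float = 600.0, r_max_um: float = 1600.0) -> Polygon:
    """Random simple star-shaped polygon (vertices at sorted angles)."""
    while True:
        angles = np.sort(rng.uniform(0.0, 2 * np.pi, n_vertices))
        if np.min(np.diff(angles)) < 1e-3:
            continue
        radii = rng.uniform(r_min_um, r_max_um, n_vertices)
        poly = Polygon(np.column_stack([radii * np.cos(angles), radii * np.sin(angles)]))
        if poly.is_valid and poly.area > 0:
            return poly


def segment_distance(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each point to a closed polyline."""
    a, b = coords[:-1], coords[1:]
    d = np.full(len(points), np.inf)
    for start, end in zip(a, b):
        ab = end - start
        t = np.clip(((points - start) @ ab) / (ab @ ab), 0.0, 1.0)
        proj = start + t[:, None] * ab
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d
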