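import numpy as np
import pytest
from shapely.geometry import box

from nicheshift.synthetic import SyntheticTissueConfig, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """One patient, two timepoints, 3 FOVs of 500 touching cells each."""
    cfg = SyntheticTissueConfig(
        n_patients=1,
        timepoints=("A", "B"),
        fovs_per_sample=3,
        n_cells_per_fov=500,
        fov_width_um=500.0,
        fov_height_um=330.0,
        leukemia_focus_sigma_um=40.0,
        seed=5,
    )
    return generate_tissue(cfg)


@pytest.fixture
def unit_square():
    return box(0, 0, 1, 1)


def random_convex_polygon(rng, center, radius):
    """Random convex polygon: convex hull of points on a jittered circle."""
    k = rng.integers(4, 9)
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = radius * rng.uniform(0.5, 1.0, k)
    pts = np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    from shapely.geometry import MultiPoint

    return MultiPoint(pts).convex_hull


def boundary_sample_min_distance(poly_a, poly_b, n=10_000):
    """Brute-force edge distance: min pairwise distance between densely
    sampled boundary points (independent of shapely's distance)."""
    from scipy.spatial import cKDTree

    def samples(p):
        ring = p.exterior
        ts = np.linspace(0, ring.length, n, endpoint=False)
        pts = [ring.interpolate(t) for t in ts]
        dense = np.array([[q.x, q.y] for q in pts])
        return np.vstack([dense, np.asarray(ring.coords)])  # vertices included

    a, b = samples(poly_a), samples(poly_b)
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return float(d.min())
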