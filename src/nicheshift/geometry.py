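"""Edge-to-edge cell geometry.

Cells in spatial transcriptomics are polygons, not points.  All distances in
this module are minimum Euclidean distances between cell boundaries
("edge-to-edge"), which — unlike centroid distances — correctly report 0 for
directly touching neighbours and never exceed the centroid distance.

Cell tables are pandas DataFrames with one row per cell and (at least) the
columns ``cell_id, fov_id, patient_id, timepoint, response, cell_type,
polygon`` where ``polygon`` holds a shapely ``Polygon`` in FOV-local µm
coordinates.  Distances are always computed within a single field of view
(FOV); neighbourhoods of cells near an FOV border are truncated by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Ring boundaries in µm used throughout: annuli 0–5, 5–15, 15–25, 25–35,
#: 35–45 around each index cell's membrane.
DEFAULT_RING_BOUNDARIES = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0)

CELL_META_COLUMNS = ("cell_id", "fov_id", "patient_id", "timepoint", "response", "cell_type")


@dataclass(frozen=True)
class RingSpec:
    """Half-open radial distance bands [lo, hi) around an index cell.

    The default bands partition [0, 45) µm into the five annuli used for
    neighbourhood composition analysis; a distance of exactly 5 µm falls in
    the second band, and distances >= the last boundary fall in no band.
    """

    boundaries: tuple[float, ...] = DEFAULT_RING_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2:
            raise ValueError("need at least two ring boundaries")
        if b[0] != 0.0:
            raise ValueError("ring boundaries must start at 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("ring boundaries must be strictly increasing")

    @property
    def n_rings(self) -> int:
        return len(self.boundaries) - 1

    @property
    def max_distance(self) -> float:
        return float(self.boundaries[-1])

    def labels(self) -> list[str]:
        b = self.boundaries
        return [f"{b[i]:g}-{b[i + 1]:g}" for i in range(self.n_rings)]


def _as_polygon(poly) -> Polygon:
    if isinstance(poly, Polygon):
        p = poly
    else:
        coords = np.asarray(poly, dtype=float)
        if coords.ndim != 2 or len(coords) < 3:
            raise ValueError("degenerate polygon: need at least 3 vertices")
        p = Polygon(coords)
    if len(p.exterior.coords) < 4:  # closed ring repeats first vertex
        raise ValueError("degenerate polygon: need at least 3 vertices")
    return p


def min_edge_distance(poly_a, poly_b) -> float:
    """Minimum distance between the edges of two cell polygons (µm).

    Returns 0 when the boundaries touch or the polygons overlap.
    """
    a, b = _as_polygon(poly_a), _as_polygon(poly_b)
    return float(shapely.distance(a, b))


def centroid_distance(poly_a, poly_b) -> float:
    """Centroid-to-centroid distance; comparison utility only."""
    a, b = _as_polygon(poly_a), _as_polygon(poly_b)
    return float(a.centroid.distance(b.centroid))


def pairwise_min_distances(cells: pd.DataFrame, cutoff: float = 45.0) -> pd.DataFrame:
    """All unordered within-FOV cell pairs with edge distance <= ``cutoff``.

    Parameters
    ----------
    cells
        Cell table for a *single* FOV.
    cutoff
        Maximum edge-to-edge distance (µm) retained.

    Returns
    -------
    DataFrame with columns ``id_a, id_b, dist_um`` (one row per unordered
    pair, ``id_a < id_b`` by table position).
    """
    if len(cells) == 0:
        raise ValueError("empty FOV: no cells to compute distances for")
    if cells["fov_id"].nunique() > 1:
        raise ValueError("pairwise_min_distances operates on a single FOV")
    geoms = np.asarray(cells["polygon"].to_numpy(), dtype=object)
    ids = cells["cell_id"].to_numpy()
    tree = STRtree(geoms)
    qi, ti = tree.query(geoms, predicate="dwithin", distance=cutoff)
    keep = qi < ti
    qi, ti = qi[keep], ti[keep]
    dist = shapely.distance(geoms[qi], geoms[ti])
    ok = dist <= cutoff
    return pd.DataFrame({"id_a": ids[qi[ok]], "id_b": ids[ti[ok]], "dist_um": dist[ok]})


def count_touching_neighbors(cell_id, distances: pd.DataFrame, touch_tol: float = 0.0) -> int:
    """Number of cells at edge distance <= ``touch_tol`` of ``cell_id``.

    ``touch_tol=0`` counts strictly touching neighbours; pass a small epsilon
    (e.g. 1e-6 µm) to absorb floating-point jitter in vertex coordinates.
    """
    m = (distances["id_a"] == cell_id) | (distances["id_b"] == cell_id)
    return int((distances.loc[m, "dist_um"] <= touch_tol).sum())


def assign_ring(distance, spec: RingSpec | None = None):
    """Ring index for an edge distance; None beyond the outermost boundary.

    Scalar in, scalar out; arrays are handled vectorised (index −1 marks
    out-of-range distances in the array form).
    """
    spec = spec or RingSpec()
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    b = np.asarray(spec.boundaries)
    idx = np.searchsorted(b, d, side="right") - 1
    idx = np.where(d >= b[-1], -1, idx)
    if np.ndim(distance) == 0:
        i = int(idx)
        return None if i < 0 else i
    return idx


def neighborhood_counts(
    cells: pd.DataFrame,
    index_type: str = "leukemia",
    spec: RingSpec | None = None,
) -> pd.DataFrame:
    """Per-index-cell ring neighbourhood composition.

    For every cell of ``index_type`` (e.g. leukemia), every other cell in the
    same FOV is binned into a ring by edge-to-edge distance and counted by
    cell type.  The index cell itself is excluded from its own rings; other
    cells of the index type count as neighbours like any other type.

    Returns a sparse long table: one row per (index cell, ring, cell type)
    with ``count > 0``, plus ``ring_total`` (all neighbours in the ring) and
    the index cell's FOV/patient/timepoint/response metadata.  Rings with no
    neighbours produce no rows.  FOVs without index cells are skipped with a
    log entry.
    """
    spec = spec or RingSpec()
    rows: list[dict] = []
    for fov, sub in cells.groupby("fov_id", sort=True):
        sub = sub.reset_index(drop=True)
        idx_mask = (sub["cell_type"] == index_type).to_numpy()
        if not idx_mask.any():
            logger.info("neighborhood_counts: FOV %s has no %s cells; skipped", fov, index_type)
            continue
        geoms = np.asarray(sub["polygon"].to_numpy(), dtype=object)
        types = sub["cell_type"].to_numpy()
        ids = sub["cell_id"].to_numpy()
        tree = STRtree(geoms)
        index_pos = np.flatnonzero(idx_mask)
        qi, ti = tree.query(geoms[index_pos], predicate="dwithin", distance=spec.max_distance)
        # qi indexes into index_pos; drop self pairs
        src = index_pos[qi]
        keep = src != ti
        src, ti = src[keep], ti[keep]
        if len(src) == 0:
            continue
        dist = shapely.distance(geoms[src], geoms[ti])
        ring = assign_ring(dist, spec)
        ok = ring >= 0
        src, ti, ring = src[ok], ti[ok], ring[ok]
        meta = {
            c: sub[c].iloc[0]
            for c in ("patient_id", "timepoint", "response")
            if c in sub.columns
        }
        tab = pd.DataFrame(
            {"index_cell_id": ids[src], "ring_index": ring, "cell_type": types[ti]}
        )
        grouped = (
            tab.groupby(["index_cell_id", "ring_index", "cell_type"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        totals = (
            tab.groupby(["index_cell_id", "ring_index"], sort=True)
            .size()
            .rename("ring_total")
            .reset_index()
        )
        grouped = grouped.merge(totals, on=["index_cell_id", "ring_index"])
        grouped.insert(1, "fov_id", fov)
        for k, v in meta.items():
            grouped[k] = v
        rows.append(grouped)
    if not rows:
        return pd.DataFrame(
            columns=["index_cell_id", "fov_id", "ring_index", "cell_type", "count", "ring_total"]
        )
    return pd.concat(rows, ignore_index=True)


def nearest_type_distances(
    cells: pd.DataFrame, ref_type: str = "leukemia"
) -> pd.DataFrame:
    """Edge distance from every non-``ref_type`` cell to its nearest
    ``ref_type`` cell, computed within FOV.

    FOVs containing no ``ref_type`` cells contribute nothing (logged).
    Returns columns ``cell_id, fov_id, cell_type, dist_um``.
    """
    out = []
    for fov, sub in cells.groupby("fov_id", sort=True):
        ref = sub[sub["cell_type"] == ref_type]
        qry = sub[sub["cell_type"] != ref_type]
        if len(ref) == 0:
            logger.info("nearest_type_distances: FOV %s has no %s cells; excluded", fov, ref_type)
            continue
        if len(qry) == 0:
            continue
        ref_geoms = np.asarray(ref["polygon"].to_numpy(), dtype=object)
        qry_geoms = np.asarray(qry["polygon"].to_numpy(), dtype=object)
        tree = STRtree(ref_geoms)
        nearest = tree.nearest(qry_geoms)
        d = shapely.distance(qry_geoms, ref_geoms[nearest])
        out.append(
            pd.DataFrame(
                {
                    "cell_id": qry["cell_id"].to_numpy(),
                    "fov_id": fov,
                    "cell_type": qry["cell_type"].to_numpy(),
                    "dist_um": d,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["cell_id", "fov_id", "cell_type", "dist_um"])
    return pd.concat(out, ignore_index=True)


@dataclass
class QCLog:
    """Removal record for the two-stage quality filter."""

    removed_cells: list = field(default_factory=list)
    removed_fovs: list = field(default_factory=list)
    n_cells_low_counts: int = 0
    n_cells_in_removed_fovs: int = 0


def qc_filter(
    cells: pd.DataFrame,
    min_transcripts: int = 20,
    min_cells_per_fov: int = 300,
) -> tuple[pd.DataFrame, QCLog]:
    """Two-stage quality filter applied before any spatial analysis.

    First removes low-quality cells (``total_counts < min_transcripts``),
    then removes whole FOVs left with fewer than ``min_cells_per_fov``
    surviving cells.  Both stages are recorded in the returned :class:`QCLog`.
    """
    log = QCLog()
    if len(cells) == 0:
        return cells.copy(), log
    low = cells["total_counts"] < min_transcripts
    log.removed_cells = cells.loc[low, "cell_id"].tolist()
    log.n_cells_low_counts = int(low.sum())
    kept = cells.loc[~low]
    fov_sizes = kept.groupby("fov_id").size()
    bad_fovs = fov_sizes[fov_sizes < min_cells_per_fov].index
    log.removed_fovs = list(bad_fovs)
    in_bad = kept["fov_id"].isin(bad_fovs)
    log.n_cells_in_removed_fovs = int(in_bad.sum())
    return kept.loc[~in_bad].reset_index(drop=True), log
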