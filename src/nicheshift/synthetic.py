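"""Synthetic multi-FOV tissues and mask fixtures with planted ground truth.

The generator emulates the data structure of a CosMx-style single-cell
spatial transcriptomics experiment on bone marrow: rectangular fields of
view (FOVs, default 985 × 657 µm) packed with touching polygonal cells,
per-cell gene count vectors drawn from type-specific Poisson profiles
(~100 counts/cell), negative-control probes at a low common background
rate, and patient / timepoint / response metadata.

Planted structure makes every downstream stage testable against a known
answer:

* proximity enrichment — a multiplier profile over distance biases which
  cells near leukemia carry a given type label while the per-FOV type
  proportions stay fixed, isolating the spatial effect from abundance;
* ligand–receptor signal — a fold-change on one gene in cells of one type
  lying within the "close" band of a leukemia cell;
* mask fixtures — nuclear/membrane/merged label rasters and truth/predicted
  pairs whose TP/FP/FN ledger at IOU 0.7 is known by construction.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box

from .geometry import nearest_type_distances
from .masks import LabelMask

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Default panel: marker genes (bone-marrow cell types), housekeeping bulk,
# inert filler, and negative-control probes.

MARKER_GENES: dict[str, list[str]] = {
    "erythroid progenitor": ["HBB", "HBA1"],
    "megakaryocyte": ["PF4", "PPBP"],
    "dendritic cell": ["IL3RA", "CD33", "LYZ"],
    "monocyte progenitor": ["MPO", "ELANE"],
    "CD14 monocyte": ["CD14", "CSF3R", "S100A9"],
    "CD16 monocyte": ["FCGR3A"],
    "NK cell": ["GNLY", "NKG7"],
    "leukemia": ["CD34", "KIT"],
    "stromal": ["CXCL12", "COL3A1"],
    "T cell": ["CD3E", "CD3D", "CD3G"],
    "B cell": ["CD19", "CD79A"],
}

SUBTYPE_MARKER_GENES: dict[str, list[str]] = {
    "T CD4 naive": ["CD4", "IL7R", "CCR7"],
    "T CD8": ["CD8A", "CD8B", "GZMK", "GZMH", "CCL5"],
    "B naive": ["MS4A1", "TCL1A"],
    "B plasma": ["JCHAIN"],
}

#: Round-2 lymphocyte subtypes -> their round-1 broad lineage.
BROAD_TYPE_OF_SUBTYPE = {
    "T CD4 naive": "T cell",
    "T CD8": "T cell",
    "B naive": "B cell",
    "B plasma": "B cell",
}

HOUSEKEEPING_GENES = [
    "ACTB", "B2M", "GAPDH", "HPRT1", "RPL13A", "TUBB", "UBC", "PTPRC", "MALAT1", "EEF1A1",
]

# Ligand/receptor genes appearing in the shipped pair table but not used as
# type markers; expressed at a low basal rate everywhere.
SIGNALING_GENES = [
    "TNFSF12", "TNFRSF12A", "TNF", "TNFRSF1A", "TGFB1", "TGFBR1", "IL7",
    "CXCR4", "FLT3LG", "FLT3", "KITLG", "CSF1", "CSF1R", "CCR5", "CCR2",
    "CCL2", "CD40LG", "CD40", "FASLG", "FAS", "IL6", "IL6R", "IL10",
    "IL10RA", "JAG1", "NOTCH1",
]

DEFAULT_TYPE_PROPORTIONS: dict[str, float] = {
    "leukemia": 0.15,
    "erythroid progenitor": 0.14,
    "megakaryocyte": 0.02,
    "dendritic cell": 0.05,
    "monocyte progenitor": 0.10,
    "CD14 monocyte": 0.12,
    "CD16 monocyte": 0.05,
    "NK cell": 0.05,
    "stromal": 0.05,
    "T CD4 naive": 0.10,
    "T CD8": 0.08,
    "B naive": 0.07,
    "B plasma": 0.02,
}

MARKER_MEAN = 8.0  # mean counts per own marker gene
BASAL_MEAN = 0.3  # mean counts per non-marker off-target gene
MARKER_OFFTARGET_MEAN = 0.02  # marker genes are near-specific to their type
HOUSEKEEPING_MEAN = 6.5  # mean counts per housekeeping gene (~100 counts/cell total)


def default_gene_panel() -> list[str]:
    genes: list[str] = []
    for g in (
        [m for ms in MARKER_GENES.values() for m in ms]
        + [m for ms in SUBTYPE_MARKER_GENES.values() for m in ms]
        + HOUSEKEEPING_GENES
        + SIGNALING_GENES
    ):
        if g not in genes:
            genes.append(g)
    return genes


def default_expression_profiles() -> dict[str, dict[str, float]]:
    """Per-type mean count per gene; ~100 total counts per cell."""
    panel = default_gene_panel()
    all_markers = {
        g
        for ms in list(MARKER_GENES.values()) + list(SUBTYPE_MARKER_GENES.values())
        for g in ms
    }
    profiles: dict[str, dict[str, float]] = {}
    for ctype in DEFAULT_TYPE_PROPORTIONS:
        prof = {
            g: (MARKER_OFFTARGET_MEAN if g in all_markers else BASAL_MEAN) for g in panel
        }
        for g in HOUSEKEEPING_GENES:
            prof[g] = HOUSEKEEPING_MEAN
        broad = BROAD_TYPE_OF_SUBTYPE.get(ctype)
        for g in MARKER_GENES.get(broad or ctype, []):
            prof[g] = MARKER_MEAN
        for g in SUBTYPE_MARKER_GENES.get(ctype, []):
            prof[g] = MARKER_MEAN
        profiles[ctype] = prof
    return profiles


# ---------------------------------------------------------------------------
# Configs


@dataclass
class EnrichmentBand:
    """Proximity multiplier for one distance band [lo_um, hi_um)."""

    lo_um: float
    hi_um: float
    multiplier: float


@dataclass
class SyntheticTissueConfig:
    """Study conditions for one synthetic multi-FOV dataset.

    ``enrichment_spec`` maps ``(cell_type, timepoint, response)`` to a list
    of :class:`EnrichmentBand`; cells of that type are preferentially placed
    (by relabelling) at distances from the nearest leukemia cell where the
    multiplier exceeds 1, without changing per-FOV type proportions.
    ``lr_signal_spec`` entries ``(gene, cell_type, fold)`` multiply the
    Poisson mean of ``gene`` in cells of ``cell_type`` within
    ``lr_close_um`` of a leukemia cell.
    """

    n_patients: int = 1
    timepoints: tuple[str, ...] = ("A", "B", "C")
    response_map: dict | None = None  # patient_id -> "responder"/"nonresponder"
    fovs_per_sample: int = 3
    fov_width_um: float = 985.0
    fov_height_um: float = 657.0
    n_cells_per_fov: int = 2000
    type_proportions: dict | None = None
    leukemia_type_name: str = "leukemia"
    enrichment_spec: dict = field(default_factory=dict)
    expression_profiles: dict | None = None
    n_negative_probes: int = 19
    negative_probe_mean: float = 0.05
    lr_signal_spec: list = field(default_factory=list)
    lr_close_um: float = 5.0
    #: Max cell radius (µm): Voronoi cells are trimmed to a disc of this
    #: radius.  None chooses 0.7·sqrt(FOV area / n cells) so that neighbouring
    #: cells keep their shared Voronoi edges and genuinely touch.
    cell_radius_um: float | None = None
    #: Leukemia cells cluster into foci (as blasts do in marrow), which keeps
    #: both near-leukemia and far (>= 30 µm) populations present in a dense
    #: FOV.  Set n_foci to 0 for spatially uniform leukemia.
    leukemia_n_foci: int = 3
    leukemia_focus_sigma_um: float = 60.0
    large_cell_types: dict = field(default_factory=lambda: {"megakaryocyte": 16.0})
    include_transcripts: bool = False
    n_background_transcripts_per_fov: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.type_proportions or DEFAULT_TYPE_PROPORTIONS
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions must sum to 1 (got {total})")
        if any(p < 0 for p in props.values()):
            raise ValueError("type proportions must be nonnegative")
        if self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise ValueError("FOV dimensions must be positive")
        if self.n_cells_per_fov <= 0 or self.fovs_per_sample <= 0 or self.n_patients <= 0:
            raise ValueError("counts must be positive")
        self.type_proportions = dict(props)
        self.expression_profiles = self.expression_profiles or default_expression_profiles()
        missing = set(self.type_proportions) - set(self.expression_profiles)
        if missing:
            raise ValueError(f"no expression profile for types: {sorted(missing)}")
        if self.response_map is None:
            # alternate responder / nonresponder across patients
            self.response_map = {
                f"P{i + 1}": ("responder" if i % 2 == 0 else "nonresponder")
                for i in range(self.n_patients)
            }


@dataclass
class Tissue:
    """Generated dataset: cell table, count matrix, optional transcripts."""

    cells: pd.DataFrame
    counts: pd.DataFrame  # indexed by cell_id; genes + negative probe columns
    transcripts: pd.DataFrame | None = None
    config: SyntheticTissueConfig | None = None

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.counts.columns if not c.startswith("NegPrb")]

    @property
    def negprobe_columns(self) -> list[str]:
        return [c for c in self.counts.columns if c.startswith("NegPrb")]


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be packed into the FOV area."""


# ---------------------------------------------------------------------------
# Placement: dart-throwing centres + reflected Voronoi, trimmed to a radius.


def _place_centers(rng, width, height, seps, max_attempts_factor=200):
    """Dart-throwing with per-centre separation radii (grid-accelerated)."""
    n = len(seps)
    order = np.argsort(seps)[::-1]  # place large cells first
    max_sep = float(np.max(seps))
    cell = max_sep if max_sep > 0 else 1.0
    nx, ny = max(1, int(width // cell)), max(1, int(height // cell))
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.empty((n, 2))
    placed_sep = np.empty(n)
    placed = 0
    attempts_left = max_attempts_factor * n
    for k in order:
        s = seps[k]
        ok = False
        while attempts_left > 0:
            attempts_left -= 1
            x = rng.uniform(0, width)
            y = rng.uniform(0, height)
            gx, gy = int(x // cell) if cell else 0, int(y // cell) if cell else 0
            gx, gy = min(gx, nx - 1), min(gy, ny - 1)
            conflict = False
            for dx in (-2, -1, 0, 1, 2):
                for dy in (-2, -1, 0, 1, 2):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        need = 0.5 * (s + placed_sep[j])
                        if (x - centers[j, 0]) ** 2 + (y - centers[j, 1]) ** 2 < need**2:
                            conflict = True
                            break
                    if conflict:
                        break
                if conflict:
                    break
            if not conflict:
                centers[placed] = (x, y)
                placed_sep[placed] = s
                grid.setdefault((gx, gy), []).append(placed)
                placed += 1
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place {n} cells in {width:g}x{height:g} µm "
                f"(placed {placed}); reduce n_cells_per_fov or cell radii"
            )
    # undo placement ordering so centres align with the requested seps
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return centers[inv]


def _voronoi_polygons(centers, width, height, trim_radius):
    """Bounded Voronoi cells (via 4-edge reflection), clipped to a disc of
    ``trim_radius`` around each centre and to the FOV rectangle."""
    pts = centers
    xm, xp = -pts[:, 0], 2 * width - pts[:, 0]
    ym, yp = -pts[:, 1], 2 * height - pts[:, 1]
    x, y = pts[:, 0], pts[:, 1]
    refl = [
        np.column_stack(c)
        for c in [
            (xm, y), (xp, y), (x, ym), (x, yp),  # edge reflections
            (xm, ym), (xm, yp), (xp, ym), (xp, yp),  # corner reflections
        ]
    ]
    allpts = np.vstack([pts] + refl)
    vor = Voronoi(allpts)
    fov_box = box(0.0, 0.0, width, height)
    polys = []
    for i in range(len(pts)):
        region = [v for v in vor.regions[vor.point_region[i]] if v != -1]
        verts = vor.vertices[region]
        # regions are convex; angular sort yields a valid simple ring
        ang = np.arctan2(verts[:, 1] - verts[:, 1].mean(), verts[:, 0] - verts[:, 0].mean())
        cell = Polygon(verts[np.argsort(ang)])
        disc = Point(pts[i]).buffer(float(trim_radius[i]), quad_segs=8)
        clipped = cell.intersection(disc).intersection(fov_box)
        if clipped.geom_type == "MultiPolygon":  # numeric sliver; keep biggest part
            clipped = max(clipped.geoms, key=lambda g: g.area)
        # snap to a 1e-9 µm grid: keeps coordinates exact well below any
        # distance tolerance and avoids overlay artifacts from 1-ulp vertices
        polys.append(shapely.set_precision(clipped, 1e-9))
    return polys


def _apportion(proportions: dict[str, float], n: int, rng) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to types."""
    types = list(proportions)
    raw = np.array([proportions[t] for t in types], dtype=float)
    raw = raw / raw.sum() * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    if rem > 0:
        frac = raw - base
        order = np.argsort(-(frac + rng.uniform(0, 1e-9, len(frac))))
        base[order[:rem]] += 1
    return dict(zip(types, base))


def _multiplier_at(bands: list[EnrichmentBand], d: np.ndarray) -> np.ndarray:
    m = np.ones_like(d)
    for band in bands:
        m = np.where((d >= band.lo_um) & (d < band.hi_um), band.multiplier, m)
    return m


def _inclusion_probabilities(w: np.ndarray, k: int) -> np.ndarray:
    """Inclusion probabilities proportional to weights, capped at 1 with the
    excess redistributed, summing exactly to k."""
    pi = np.minimum(1.0, k * w / w.sum())
    for _ in range(50):
        over = pi >= 1.0
        slack = k - over.sum()
        free = ~over
        if slack <= 0 or not free.any():
            break
        scaled = np.minimum(1.0, slack * w[free] / w[free].sum())
        if np.allclose(pi[free], scaled):
            pi[free] = scaled
            break
        pi[free] = scaled
    return pi


def _systematic_sample(rng, pi: np.ndarray) -> np.ndarray:
    """Systematic (Madow) sampling: selects round(sum(pi)) items with
    inclusion probability exactly ``pi`` (all pi <= 1)."""
    order = rng.permutation(len(pi))
    c = np.cumsum(pi[order])
    k = int(round(c[-1]))
    targets = rng.uniform(0, 1) + np.arange(k)
    idx = np.searchsorted(c, targets)
    idx = np.clip(idx, 0, len(pi) - 1)
    return order[np.unique(idx)]


def _assign_types_one_fov(rng, candidates, dists_to_leuk, type_counts, enrichment):
    """Distance-biased type relabelling at fixed per-FOV type counts.

    ``candidates`` are raster positions still needing a type;
    ``dists_to_leuk`` is indexed by raster position.  Enriched types pick
    first via systematic sampling with inclusion probabilities proportional
    to the multiplier profile, so a planted multiplier m is realized as an
    in-band vs out-of-band rate ratio of m; remaining types fill uniformly,
    preserving per-FOV type proportions exactly.
    """
    assigned: dict[int, str] = {}
    remaining = np.asarray(candidates, dtype=int)
    ordered = sorted(type_counts, key=lambda t: (t not in enrichment, t))
    for t in ordered:
        k = min(type_counts[t], len(remaining))
        if k == 0:
            continue
        if t in enrichment:
            w = _multiplier_at(enrichment[t], dists_to_leuk[remaining])
            w[~np.isfinite(w)] = 1.0
            pi = _inclusion_probabilities(w, k)
            idx = _systematic_sample(rng, pi)
        else:
            idx = rng.choice(len(remaining), size=k, replace=False)
        for i in remaining[idx]:
            assigned[int(i)] = t
        remaining = np.delete(remaining, idx)
    if len(remaining):
        filler = max(type_counts, key=type_counts.get)
        for i in remaining:
            assigned[int(i)] = filler
    return assigned


def generate_tissue(config: SyntheticTissueConfig) -> Tissue:
    """Generate a deterministic multi-FOV synthetic tissue.

    Returns a :class:`Tissue` with one polygonal cell per row, Poisson gene
    counts per cell, and (optionally) per-transcript points sampled uniformly
    inside each cell's polygon.
    """
    rng = np.random.default_rng(config.seed)
    props = config.type_proportions
    profiles = config.expression_profiles
    panel = sorted({g for prof in profiles.values() for g in prof})
    neg_cols = [f"NegPrb{i + 1:02d}" for i in range(config.n_negative_probes)]
    leuk = config.leukemia_type_name

    cell_rows = []
    count_blocks = []
    transcript_rows = []
    fov_counter = 0
    for p in range(config.n_patients):
        patient = f"P{p + 1}"
        response = config.response_map[patient]
        for tp in config.timepoints:
            for f in range(config.fovs_per_sample):
                fov_counter += 1
                fov_id = f"F{fov_counter:03d}"
                n = config.n_cells_per_fov
                type_counts = _apportion(props, n, rng)
                # large types occupy dedicated large slots fixed at placement
                large = {
                    t: r for t, r in config.large_cell_types.items() if type_counts.get(t, 0) > 0
                }
                spacing = math.sqrt(config.fov_width_um * config.fov_height_um / n)
                base_radius = (
                    config.cell_radius_um if config.cell_radius_um is not None else 0.7 * spacing
                )
                seps = np.full(n, 0.68 * spacing)
                trim = np.full(n, base_radius)
                pos = 0
                large_positions: dict[str, np.ndarray] = {}
                for t, r in large.items():
                    k = type_counts[t]
                    seps[pos : pos + k] = 2.2 * r  # keep neighbours off the full disc
                    trim[pos : pos + k] = r
                    large_positions[t] = np.arange(pos, pos + k)
                    pos += k
                centers = _place_centers(rng, config.fov_width_um, config.fov_height_um, seps)
                polys = _voronoi_polygons(centers, config.fov_width_um, config.fov_height_um, trim)

                types = np.empty(n, dtype=object)
                large_all = (
                    np.concatenate(list(large_positions.values()))
                    if large_positions
                    else np.empty(0, dtype=int)
                )
                for t, idx in large_positions.items():
                    types[idx] = t
                small_positions = np.setdiff1d(np.arange(n), large_all)
                small_counts = {t: c for t, c in type_counts.items() if t not in large}
                # leukemia placed in foci (or uniformly when n_foci == 0)
                n_leuk = small_counts.pop(leuk, 0)
                if n_leuk and config.leukemia_n_foci > 0:
                    foci = np.column_stack(
                        [
                            rng.uniform(0, config.fov_width_um, config.leukemia_n_foci),
                            rng.uniform(0, config.fov_height_um, config.leukemia_n_foci),
                        ]
                    )
                    cand = centers[small_positions]
                    d2 = ((cand[:, None, :] - foci[None, :, :]) ** 2).sum(axis=2).min(axis=1)
                    w = np.exp(-0.5 * d2 / config.leukemia_focus_sigma_um**2) + 0.02
                    pi = _inclusion_probabilities(w, n_leuk)
                    leuk_idx = small_positions[_systematic_sample(rng, pi)]
                elif n_leuk:
                    leuk_idx = rng.choice(small_positions, size=n_leuk, replace=False)
                else:
                    leuk_idx = np.empty(0, dtype=int)
                types[leuk_idx] = leuk
                others = np.setdiff1d(small_positions, leuk_idx)
                # distances from candidate cells to nearest leukemia polygon
                if n_leuk and len(others):
                    leuk_geoms = np.asarray([polys[i] for i in leuk_idx], dtype=object)
                    other_geoms = np.asarray([polys[i] for i in others], dtype=object)
                    tree = shapely.strtree.STRtree(leuk_geoms)
                    nearest = tree.nearest(other_geoms)
                    d_near = shapely.distance(other_geoms, leuk_geoms[nearest])
                else:
                    d_near = np.full(len(others), np.inf)
                enrichment = {
                    t: bands
                    for (t, spec_tp, spec_resp), bands in config.enrichment_spec.items()
                    if spec_tp == tp and spec_resp == response and t in small_counts
                }
                d_all = np.full(n, np.inf)
                d_all[others] = d_near
                assigned = _assign_types_one_fov(rng, others, d_all, small_counts, enrichment)
                for i, t in assigned.items():
                    types[i] = t

                # expression
                lam = np.zeros((n, len(panel)))
                gene_pos = {g: j for j, g in enumerate(panel)}
                for t in set(types):
                    rowsel = types == t
                    prof = profiles[t]
                    lam[rowsel] = [prof.get(g, 0.0) for g in panel]
                for gene, t, fold in config.lr_signal_spec:
                    sel = (types == t) & (d_all <= config.lr_close_um)
                    if gene in gene_pos:
                        lam[sel, gene_pos[gene]] *= fold
                counts = rng.poisson(lam)
                negs = rng.poisson(config.negative_probe_mean, size=(n, len(neg_cols)))

                ids = [f"{patient}-{tp}-{fov_id}-{i:04d}" for i in range(n)]
                areas = np.array([pg.area for pg in polys])
                cell_rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": ids,
                            "fov_id": fov_id,
                            "patient_id": patient,
                            "timepoint": tp,
                            "response": response,
                            "cell_type": types,
                            "polygon": polys,
                            "area_um2": areas,
                            "total_counts": counts.sum(axis=1),
                        }
                    )
                )
                block = pd.DataFrame(counts, columns=panel, index=ids)
                block[neg_cols] = negs
                count_blocks.append(block)

                if config.include_transcripts:
                    transcript_rows.append(
                        _sample_transcripts(rng, ids, polys, counts, panel, fov_id)
                    )
                    nbg = config.n_background_transcripts_per_fov
                    if nbg:
                        bx = rng.uniform(0, config.fov_width_um, nbg)
                        by = rng.uniform(0, config.fov_height_um, nbg)
                        bg = pd.DataFrame(
                            {
                                "gene": rng.choice(panel, nbg),
                                "x_um": bx,
                                "y_um": by,
                                "fov_id": fov_id,
                                "true_cell_id": "",
                            }
                        )
                        transcript_rows.append(bg)

    cells = pd.concat(cell_rows, ignore_index=True)
    counts = pd.concat(count_blocks)
    counts.index.name = "cell_id"
    transcripts = pd.concat(transcript_rows, ignore_index=True) if transcript_rows else None
    return Tissue(cells=cells, counts=counts, transcripts=transcripts, config=config)


def _sample_transcripts(rng, ids, polys, counts, panel, fov_id):
    rows = []
    for i, (cid, pg) in enumerate(zip(ids, polys)):
        total = counts[i].sum()
        if total == 0:
            continue
        minx, miny, maxx, maxy = pg.bounds
        pts_x, pts_y = [], []
        need = int(total)
        while need > 0:
            m = max(32, 2 * need)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            inside = shapely.contains_xy(pg, xs, ys)
            take = min(need, inside.sum())
            pts_x.append(xs[inside][:take])
            pts_y.append(ys[inside][:take])
            need -= take
        xs = np.concatenate(pts_x)
        ys = np.concatenate(pts_y)
        genes = np.repeat(panel, counts[i])
        rows.append(
            pd.DataFrame(
                {"gene": genes, "x_um": xs, "y_um": ys, "fov_id": fov_id, "true_cell_id": cid}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene", "x_um", "y_um", "fov_id", "true_cell_id"])
    return pd.concat(rows, ignore_index=True)


def tissue_config_to_yaml(config: SyntheticTissueConfig, path) -> None:
    """Serialise a tissue config to YAML (enrichment bands flattened)."""
    import dataclasses

    import yaml

    raw = dataclasses.asdict(config)
    raw["timepoints"] = list(config.timepoints)
    raw["enrichment_spec"] = [
        {
            "cell_type": ct, "timepoint": tp, "response": resp,
            "bands": [dataclasses.asdict(b) for b in bands],
        }
        for (ct, tp, resp), bands in config.enrichment_spec.items()
    ]
    raw["lr_signal_spec"] = [list(entry) for entry in config.lr_signal_spec]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def tissue_config_from_yaml(path) -> SyntheticTissueConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["timepoints"] = tuple(raw.get("timepoints", ("A", "B", "C")))
    raw["enrichment_spec"] = {
        (e["cell_type"], e["timepoint"], e["response"]): [
            EnrichmentBand(**b) for b in e["bands"]
        ]
        for e in raw.get("enrichment_spec", [])
    }
    raw["lr_signal_spec"] = [tuple(entry) for entry in raw.get("lr_signal_spec", [])]
    return SyntheticTissueConfig(**raw)


# ---------------------------------------------------------------------------
# Mask fixtures


@dataclass
class MaskFixtureSpec:
    """Recipe for a truth/predicted mask pair with a known error ledger."""

    shape: tuple[int, int] = (256, 256)
    n_true_cells: int = 30
    n_split_errors: int = 0
    n_merge_errors: int = 0
    n_missed: int = 0
    n_spurious: int = 0
    boundary_jitter_px: float = 0.0
    cell_radius_px: int = 8
    nucleus_radius_px: int = 4
    expansion_px: float = 3.0
    membrane_missing_fraction: float = 0.0
    pixel_size_um: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        affected = self.n_split_errors + 2 * self.n_merge_errors + self.n_missed
        if affected > self.n_true_cells:
            raise ValueError("error counts exceed n_true_cells")
        if self.boundary_jitter_px > 0 and self.cell_radius_px < 6:
            raise ValueError("jitter requires cell_radius_px >= 6 to keep unaffected IOU > 0.7")
        if not 0 <= self.membrane_missing_fraction <= 1:
            raise ValueError("membrane_missing_fraction must be in [0, 1]")


def _place_disc_centers(rng, shape, n, min_sep, margin):
    h, w = shape
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise PackingError("grid too small for requested cell radius")
    centers = []
    attempts = 400 * max(n, 1)
    while len(centers) < n and attempts > 0:
        attempts -= 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    if len(centers) < n:
        raise PackingError(f"grid too small for {n} cells of separation {min_sep}")
    return np.array(centers)


def _draw_disc(arr, cx, cy, r, label):
    h, w = arr.shape
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    arr[y0:y1, x0:x1][sel] = label


def generate_mask_pair(spec: MaskFixtureSpec):
    """Truth mask, perturbed predicted mask, and the expected TP/FP/FN ledger
    at IOU 0.7 implied by the planted split/merge/miss/spurious errors.

    A split halves one truth cell into two predicted labels (each ~0.5 IOU);
    a merge gives two truth cells one predicted label; a miss removes a
    predicted cell; a spurious adds a predicted cell on background.  Small
    whole-cell jitter (<= 1 px) leaves unaffected cells above the threshold.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.cell_radius_px
    centers = _place_disc_centers(rng, spec.shape, spec.n_true_cells, 2 * r + 3, r + 2)
    truth = np.zeros(spec.shape, dtype=np.int64)
    for i, (cx, cy) in enumerate(centers, start=1):
        _draw_disc(truth, cx, cy, r, i)

    labels = np.arange(1, spec.n_true_cells + 1)
    rng.shuffle(labels)
    cursor = 0
    split_labels = labels[cursor : cursor + spec.n_split_errors]; cursor += spec.n_split_errors
    merge_labels = labels[cursor : cursor + 2 * spec.n_merge_errors]; cursor += 2 * spec.n_merge_errors
    miss_labels = labels[cursor : cursor + spec.n_missed]; cursor += spec.n_missed
    affected = set(split_labels) | set(merge_labels) | set(miss_labels)

    pred = np.zeros_like(truth)
    next_label = 1
    for lab in range(1, spec.n_true_cells + 1):
        if lab in miss_labels:
            continue
        sel = truth == lab
        if lab in split_labels:
            cx = centers[lab - 1, 0]
            left = sel & (np.arange(spec.shape[1])[None, :] < cx)
            right = sel & ~left
            pred[left] = next_label; next_label += 1
            pred[right] = next_label; next_label += 1
        else:
            if spec.boundary_jitter_px > 0 and lab not in affected:
                dx, dy = rng.integers(-1, 2, 2) * min(1, int(np.ceil(spec.boundary_jitter_px)))
                shifted = np.zeros_like(sel)
                src = sel
                shifted = np.roll(np.roll(src, dy, axis=0), dx, axis=1)
                pred[shifted & (pred == 0)] = next_label
            else:
                pred[sel] = next_label
            next_label += 1
    # merges: pairs of truth cells share one predicted label
    for k in range(spec.n_merge_errors):
        a, b = merge_labels[2 * k], merge_labels[2 * k + 1]
        lab_a = np.unique(pred[truth == a]); lab_b = np.unique(pred[truth == b])
        lab_a = lab_a[lab_a > 0][0]; lab_b = lab_b[lab_b > 0][0]
        pred[pred == lab_b] = lab_a
    # spurious predictions on background
    free_margin = r + 2
    for _ in range(spec.n_spurious):
        for _attempt in range(2000):
            cx = rng.uniform(free_margin, spec.shape[1] - free_margin)
            cy = rng.uniform(free_margin, spec.shape[0] - free_margin)
            yy, xx = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
            sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            if not (truth[sel].any() or pred[sel].any()):
                pred[sel] = next_label
                next_label += 1
                break
        else:
            raise PackingError("no room for spurious cell")

    lost = spec.n_split_errors + 2 * spec.n_merge_errors + spec.n_missed
    expected = {
        "TP": spec.n_true_cells - lost,
        "FP": 2 * spec.n_split_errors + spec.n_merge_errors + spec.n_spurious,
        "FN": lost,
    }
    return (
        LabelMask(truth, spec.pixel_size_um),
        LabelMask(pred, spec.pixel_size_um),
        expected,
    )


def plant_nucleus_membrane_pair(spec: MaskFixtureSpec):
    """Nuclear mask, membrane mask, and the true merged single-cell mask.

    Every nucleus lies inside exactly one truth cell.  A configurable
    fraction of cells lack a membrane label (emulating weak or absent
    membrane staining); their truth cell is the nucleus dilated by
    ``expansion_px``.  Cells are spaced so expansions never collide, making
    the merged truth exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    r_cell = spec.cell_radius_px
    r_nuc = spec.nucleus_radius_px
    r_exp = spec.nucleus_radius_px + spec.expansion_px
    reach = max(r_cell, r_exp)
    centers = _place_disc_centers(rng, spec.shape, spec.n_true_cells, 2 * reach + 3, reach + 2)
    nuclei = np.zeros(spec.shape, dtype=np.int64)
    membranes = np.zeros_like(nuclei)
    merged = np.zeros_like(nuclei)
    has_membrane = rng.uniform(size=spec.n_true_cells) >= spec.membrane_missing_fraction
    for i, (cx, cy) in enumerate(centers, start=1):
        _draw_disc(nuclei, cx, cy, r_nuc, i)
        if has_membrane[i - 1]:
            _draw_disc(membranes, cx, cy, r_cell, i)
            _draw_disc(merged, cx, cy, r_cell, i)
        else:
            _draw_disc(merged, cx, cy, r_exp, i)
    psz = spec.pixel_size_um
    return LabelMask(nuclei, psz), LabelMask(membranes, psz), LabelMask(merged, psz)


# ---------------------------------------------------------------------------
# Model-level simulator for the neighbourhood count model


def simulate_neighborhood_counts(
    n_fovs_per_group: int = 5,
    index_cells_per_fov: int = 200,
    rings: int = 5,
    timepoints: tuple[str, str] = ("A", "B"),
    baseline_rate: float = 0.08,
    rr_b_vs_a_responders: float = 1.0,
    fov_sd: float = 0.3,
    ring_total_mean: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a neighbourhood count table straight from the Poisson mixed
    model: count ~ Poisson(ring_total · rate), log rate = log(baseline) +
    log(RR)·[responder, timepoint B] + FOV intercept.

    One FOV group exists per (response, timepoint) combination ×
    ``n_fovs_per_group``; the planted rate ratio applies to responders at the
    second timepoint across all rings, matching the "responders B vs A"
    contrast.  Used for parameter-recovery and calibration experiments.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fov_no = 0
    for resp in ("nonresponder", "responder"):
        for tp in timepoints:
            for f in range(n_fovs_per_group):
                fov_no += 1
                fov = f"F{fov_no:03d}"
                u = rng.normal(0, fov_sd)
                rate = baseline_rate * math.exp(u)
                if resp == "responder" and tp == timepoints[1]:
                    rate *= rr_b_vs_a_responders
                n_rows = index_cells_per_fov * rings
                ring_total = rng.poisson(ring_total_mean, n_rows) + 1
                count = rng.poisson(ring_total * rate)
                rows.append(
                    pd.DataFrame(
                        {
                            "index_cell_id": np.repeat(
                                [f"{fov}-{i:04d}" for i in range(index_cells_per_fov)], rings
                            ),
                            "fov_id": fov,
                            "ring_index": np.tile(np.arange(rings), index_cells_per_fov),
                            "cell_type": "query",
                            "count": count,
                            "ring_total": ring_total,
                            "patient_id": f"{resp[:1]}{f % 2}",
                            "timepoint": tp,
                            "response": resp,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
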