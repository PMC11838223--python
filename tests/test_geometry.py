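"""Edge-to-edge distances, rings, neighbourhood counts and QC filters."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon, box

from nicheshift.geometry import (
    RingSpec,
    assign_ring,
    centroid_distance,
    count_touching_neighbors,
    min_edge_distance,
    neighborhood_counts,
    pairwise_min_distances,
    qc_filter,
)
from conftest import boundary_sample_min_distance, random_convex_polygon


def _cells(polys, types=None, fov="F1", **meta):
    n = len(polys)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "fov_id": fov,
            "patient_id": meta.get("patient", "P1"),
            "timepoint": meta.get("timepoint", "A"),
            "response": meta.get("response", "responder"),
            "cell_type": types if types is not None else ["t"] * n,
            "polygon": polys,
        }
    )


class TestMinEdgeDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (box(0, 0, 1, 1), box(3, 0, 4, 1), 2.0),  # facing parallel edges
            (box(0, 0, 1, 1), box(1, 0, 2, 1), 0.0),  # shared edge
            (box(0, 0, 1, 1), box(2, 2, 3, 3), np.sqrt(2)),  # corner to corner
            (box(0, 0, 2, 2), box(1, 1, 3, 3), 0.0),  # overlapping
        ],
    )
    def test_known_configurations(self, a, b, expected):
        assert min_edge_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            min_edge_distance([(0, 0), (1, 1)], box(0, 0, 1, 1))

    def test_agrees_with_boundary_sampling_oracle(self):
        """Random polygon pairs: shapely edge distance vs dense boundary
        sampling; also symmetry and the centroid >= edge inequality."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_convex_polygon(rng, rng.uniform(0, 50, 2), rng.uniform(2, 8))
            b = random_convex_polygon(rng, rng.uniform(0, 50, 2), rng.uniform(2, 8))
            d = min_edge_distance(a, b)
            assert d == pytest.approx(min_edge_distance(b, a), abs=1e-12)
            if d > 0:
                assert d == pytest.approx(
                    boundary_sample_min_distance(a, b, n=3000), abs=1e-3 * max(1, d)
                )
            assert centroid_distance(a, b) >= d - 1e-12


class TestPairwiseDistances:
    def test_collinear_cells_within_cutoff(self):
        polys = [box(x, 0, x + 4, 4) for x in (0, 14, 28)]  # 10 µm gaps
        d = pairwise_min_distances(_cells(polys), cutoff=45)
        assert len(d) == 3
        assert sorted(d["dist_um"].round(6)) == [10.0, 10.0, 24.0]

    def test_cutoff_excludes_far_pairs(self):
        polys = [box(0, 0, 4, 4), box(14, 0, 18, 4)]
        d = pairwise_min_distances(_cells(polys), cutoff=5)
        assert len(d) == 0

    def test_empty_fov_raises(self):
        with pytest.raises(ValueError):
            pairwise_min_distances(_cells([]))

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(7)
        polys = [
            random_convex_polygon(rng, rng.uniform(0, 300, 2), rng.uniform(2, 6))
            for _ in range(200)
        ]
        cells = _cells(polys)
        d = pairwise_min_distances(cells, cutoff=45)
        got = {tuple(sorted((r.id_a, r.id_b))): r.dist_um for r in d.itertuples()}
        expect = {}
        for i in range(200):
            for k in range(i + 1, 200):
                dist = float(shapely.distance(polys[i], polys[k]))
                if dist <= 45:
                    expect[tuple(sorted((f"c{i}", f"c{k}")))] = dist
        assert set(got) == set(expect)
        for key in expect:
            assert got[key] == pytest.approx(expect[key], abs=1e-6)


class TestTouchingNeighbors:
    def test_isolated_cell(self):
        polys = [box(0, 0, 1, 1), box(10, 10, 11, 11)]
        d = pairwise_min_distances(_cells(polys))
        assert count_touching_neighbors("c0", d) == 0

    def test_two_shared_edges(self):
        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(-1, 0, 0, 1)]
        d = pairwise_min_distances(_cells(polys))
        assert count_touching_neighbors("c0", d) == 2

    def test_dense_monolayer_mode_at_least_three(self, small_tissue):
        """Voronoi-packed tissue: the modal number of directly touching
        neighbours is >= 3 (three equidistant neighbours is typical)."""
        sub = small_tissue.cells[small_tissue.cells["fov_id"] == "F001"]
        d = pairwise_min_distances(sub)
        touches = [count_touching_neighbors(c, d, touch_tol=1e-6) for c in sub["cell_id"]]
        values, counts = np.unique(touches, return_counts=True)
        assert values[np.argmax(counts)] >= 3


class TestRings:
    def test_default_boundaries(self):
        spec = RingSpec()
        assert spec.boundaries == (0.0, 5.0, 15.0, 25.0, 35.0, 45.0)
        assert spec.n_rings == 5

    @pytest.mark.parametrize(
        "distance,expected", [(0.0, 0), (4.999, 0), (5.0, 1), (14.999, 1), (15.0, 2), (44.9, 4), (45.0, None), (46.0, None)]
    )
    def test_half_open_assignment(self, distance, expected):
        assert assign_ring(distance) == expected

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            assign_ring(-0.1)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            RingSpec((5.0, 15.0))
        with pytest.raises(ValueError):
            RingSpec((0.0, 5.0, 5.0))


class TestNeighborhoodCounts:
    def test_single_neighbor_in_second_ring(self):
        polys = [box(0, 0, 4, 4), box(11, 0, 15, 4)]  # edge distance 7
        cells = _cells(polys, types=["leukemia", "T"])
        table = neighborhood_counts(cells)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["ring_index"], row["cell_type"], row["count"], row["ring_total"]) == (1, "T", 1, 1)

    def test_duplicate_neighbor_counts_twice(self):
        polys = [box(0, 0, 4, 4), box(11, 0, 15, 4), box(11, 0, 15, 4)]
        cells = _cells(polys, types=["leukemia", "T", "T"])
        table = neighborhood_counts(cells)
        assert table["count"].sum() == 2

    def test_index_type_neighbors_are_counted(self):
        polys = [box(0, 0, 4, 4), box(11, 0, 15, 4)]
        cells = _cells(polys, types=["leukemia", "leukemia"])
        table = neighborhood_counts(cells)
        assert set(table["cell_type"]) == {"leukemia"}
        assert len(table) == 2  # each leukemia cell sees the other

    def test_ring_totals_are_row_sums(self, small_tissue):
        sub = small_tissue.cells[small_tissue.cells["fov_id"] == "F001"]
        table = neighborhood_counts(sub)
        sums = table.groupby(["index_cell_id", "ring_index"]).agg(
            total=("count", "sum"), rt=("ring_total", "first")
        )
        assert (sums["total"] == sums["rt"]).all()

    def test_removing_a_type_removes_its_rows(self, small_tissue):
        sub = small_tissue.cells[small_tissue.cells["fov_id"] == "F001"]
        full = neighborhood_counts(sub)
        reduced = neighborhood_counts(sub[sub["cell_type"] != "NK cell"])
        assert "NK cell" not in set(reduced["cell_type"])
        assert set(full["cell_type"]) - set(reduced["cell_type"]) == {"NK cell"}

    def test_fov_without_index_cells_skipped(self):
        polys = [box(0, 0, 4, 4), box(11, 0, 15, 4)]
        cells = _cells(polys, types=["T", "T"])
        assert len(neighborhood_counts(cells)) == 0


class TestRingProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_rings_partition_the_axis(self, d):
        """Every nonnegative distance falls in exactly one half-open band,
        or none beyond the outer boundary."""
        spec = RingSpec()
        ring = assign_ring(d, spec)
        if d >= spec.max_distance:
            assert ring is None
        else:
            lo, hi = spec.boundaries[ring], spec.boundaries[ring + 1]
            assert lo <= d < hi

    @given(
        st.floats(0, 50), st.floats(0, 50), st.floats(1, 10), st.floats(1, 10),
        st.floats(0, 50), st.floats(0, 50),
    )
    @settings(derandomize=True, max_examples=100)
    def test_distance_symmetric_nonnegative(self, x1, y1, w1, w2, x2, y2):
        a = box(x1, y1, x1 + w1, y1 + w1)
        b = box(x2, y2, x2 + w2, y2 + w2)
        d = min_edge_distance(a, b)
        assert d >= 0
        assert d == min_edge_distance(b, a)
        assert a.intersects(b) == (d == 0)


class TestQcFilter:
    def _tissue_frame(self, counts_per_cell, fov_sizes):
        rows = []
        i = 0
        for fov, n in fov_sizes.items():
            for _ in range(n):
                rows.append({"cell_id": f"c{i}", "fov_id": fov, "total_counts": counts_per_cell})
                i += 1
        return pd.DataFrame(rows)

    def test_transcript_boundary(self):
        cells = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "fov_id": ["F1", "F1"],
                "total_counts": [19, 20],
            }
        )
        kept, log = qc_filter(cells, min_cells_per_fov=1)
        assert list(kept["cell_id"]) == ["b"]
        assert log.removed_cells == ["a"]

    def test_fov_size_boundary(self):
        cells = pd.concat(
            [self._tissue_frame(50, {"F1": 299}), self._tissue_frame(50, {"F2": 300})],
            ignore_index=True,
        )
        cells["cell_id"] = [f"c{i}" for i in range(len(cells))]
        kept, log = qc_filter(cells)
        assert set(kept["fov_id"]) == {"F2"}
        assert log.removed_fovs == ["F1"]
        assert log.n_cells_in_removed_fovs == 299

    def test_stage_order_cells_before_fovs(self):
        # 300 cells but one below the count threshold: the FOV drops to 299
        cells = self._tissue_frame(50, {"F1": 300})
        cells.loc[0, "total_counts"] = 19
        kept, log = qc_filter(cells)
        assert len(kept) == 0
        assert log.n_cells_low_counts == 1
        assert log.removed_fovs == ["F1"]

    def test_empty_input(self):
        kept, log = qc_filter(pd.DataFrame(columns=["cell_id", "fov_id", "total_counts"]))
        assert len(kept) == 0
        assert log.removed_cells == [] and log.removed_fovs == []
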