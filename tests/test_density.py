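"""Nearest-distance samples, KDEs, shift curves, permutation background."""

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.stats import norm
from shapely.geometry import box

from nicheshift.density import (
    DEFAULT_GRID,
    density_shift_test,
    estimate_pdf,
    flag_shift,
    min_distance_sample,
    observed_shift,
    permutation_background,
    planted_shift_simulation,
)


def _cells(polys, types, fovs=None, timepoint="A", patient="P1"):
    n = len(polys)
    return pd.DataFrame(
        {
            "cell_id": [f"{timepoint}{i}" for i in range(n)],
            "fov_id": fovs if fovs is not None else ["F1"] * n,
            "patient_id": patient,
            "timepoint": timepoint,
            "response": "responder",
            "cell_type": types,
            "polygon": polys,
        }
    )


class TestMinDistanceSample:
    def test_hand_built_distances(self):
        polys = [box(0, 0, 4, 4), box(7, 0, 10, 4), box(11, 0, 14, 4)]
        cells = _cells(polys, ["leukemia", "T", "T"])
        s = min_distance_sample(cells, "T")
        assert sorted(s.values.round(6)) == [3.0, 7.0]

    def test_pooling_over_fovs(self):
        polys = [box(0, 0, 4, 4), box(7, 0, 10, 4), box(0, 0, 4, 4), box(11, 0, 14, 4)]
        cells = _cells(polys, ["leukemia", "T", "leukemia", "T"], fovs=["F1", "F1", "F2", "F2"])
        s = min_distance_sample(cells, "T")
        assert sorted(s.values.round(6)) == [3.0, 7.0]
        assert s.per_fov_n == {"F1": 1, "F2": 1}

    def test_matches_all_pairs_oracle(self, small_tissue):
        sub = small_tissue.cells[
            (small_tissue.cells.timepoint == "A") & (small_tissue.cells.fov_id == "F001")
        ]
        s = min_distance_sample(sub, "T CD8")
        leuk = np.asarray(
            sub.loc[sub.cell_type == "leukemia", "polygon"].to_numpy(), dtype=object
        )
        qry = sub[sub.cell_type == "T CD8"]
        expect = {
            cid: float(shapely.distance(np.asarray([p] * len(leuk), dtype=object), leuk).min())
            for cid, p in zip(qry.cell_id, qry.polygon)
        }
        assert len(s.values) == len(expect)
        assert np.allclose(np.sort(s.values), np.sort(list(expect.values())))

    def test_unusable_without_query_cells(self):
        cells = _cells([box(0, 0, 4, 4)], ["leukemia"])
        assert not min_distance_sample(cells, "T").usable

    def test_mixed_sample_rejected(self):
        cells = pd.concat(
            [
                _cells([box(0, 0, 4, 4)], ["leukemia"], timepoint="A"),
                _cells([box(0, 0, 4, 4)], ["leukemia"], timepoint="B"),
            ]
        )
        with pytest.raises(ValueError):
            min_distance_sample(cells, "T")


class TestEstimatePdf:
    def test_degenerate_sample_peaks_at_value(self):
        pdf = estimate_pdf(np.full(50, 10.0), DEFAULT_GRID)
        assert DEFAULT_GRID[np.argmax(pdf)] == pytest.approx(10.0, abs=0.1)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            estimate_pdf(np.array([3.0]), DEFAULT_GRID)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(22, 4, 800).clip(0.1, 44)
        grid = np.linspace(0, 45, 512)
        pdf = estimate_pdf(vals, grid)
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=0.05)

    def test_kde_close_to_analytic_mixture(self):
        """At n = 5000 the KDE is within 0.1·max density of the true mixture
        density (sup-norm, interior of the support)."""
        rng = np.random.default_rng(1)
        n = 5000
        comp = rng.uniform(size=n) < 0.5
        vals = np.where(comp, rng.normal(20, 3.0, n), rng.normal(28, 4.0, n))
        grid = np.linspace(0, 45, 512)
        truth = 0.5 * norm.pdf(grid, 20, 3.0) + 0.5 * norm.pdf(grid, 28, 4.0)
        pdf = estimate_pdf(vals, grid)
        assert np.max(np.abs(pdf - truth)) < 0.1 * truth.max()


class TestObservedShift:
    def test_identical_pdfs(self):
        p = np.ones(10)
        assert np.all(observed_shift(p, p) == 0)

    def test_sign_pattern_and_zero_integral(self):
        grid = np.linspace(0, 45, 512)
        a = norm.pdf(grid, 2, 1)
        b = norm.pdf(grid, 40, 1)
        s = observed_shift(a, b)
        assert s[np.argmin(np.abs(grid - 2))] > 0
        assert s[np.argmin(np.abs(grid - 40))] < 0
        assert np.trapezoid(s, grid) == pytest.approx(0.0, abs=0.05)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            observed_shift(np.ones(5), np.ones(6))


def _two_timepoint_tissue(seed=0):
    from nicheshift.synthetic import SyntheticTissueConfig, generate_tissue

    cfg = SyntheticTissueConfig(
        n_patients=1, timepoints=("A", "B"), fovs_per_sample=3, n_cells_per_fov=400,
        fov_width_um=450, fov_height_um=300, leukemia_focus_sigma_um=40.0, seed=seed,
    )
    return generate_tissue(cfg).cells


class TestPermutationBackground:
    def test_single_permutation_rejected(self):
        cells = _two_timepoint_tissue()
        a = cells[cells.timepoint == "A"]
        b = cells[cells.timepoint == "B"]
        with pytest.raises(ValueError):
            permutation_background(a, b, "T CD8", j=1)

    def test_seeded_determinism(self):
        cells = _two_timepoint_tissue()
        a = cells[cells.timepoint == "A"]
        b = cells[cells.timepoint == "B"]
        bg1 = permutation_background(a, b, "T CD8", j=10, seed=4)
        bg2 = permutation_background(a, b, "T CD8", j=10, seed=4)
        assert np.array_equal(bg1.shifts, bg2.shifts)

    def test_draw_sizes_respect_per_fov_counts(self):
        cells = _two_timepoint_tissue()
        a = cells[cells.timepoint == "A"]
        s = min_distance_sample(a, "T CD8")
        # every FOV must have K >= N by construction here
        assert all(s.per_fov_k[f] >= n for f, n in s.per_fov_n.items())


class TestFlagShift:
    def _background(self):
        from nicheshift.density import PermutationBackground

        grid = np.linspace(0, 45, 10)
        shifts = np.vstack([np.zeros(10), np.ones(10) * 0.2, -np.ones(10) * 0.2])
        return PermutationBackground(
            grid=grid, shifts=shifts, mean=shifts.mean(0), sd=shifts.std(0, ddof=1),
            j=3, seed=None,
        )

    def test_shift_equal_to_mean_no_flags(self):
        bg = self._background()
        res = flag_shift(bg.mean.copy(), bg)
        assert not res.flags.any()

    def test_point_beyond_one_sd_flagged(self):
        bg = self._background()
        s = bg.mean.copy()
        s[3] = bg.mean[3] + 1.5 * bg.sd[3]
        res = flag_shift(s, bg)
        assert res.flags[3] and res.flags.sum() == 1


class TestPlantedShift:
    def test_fraction_zero_is_identity(self):
        cells = _two_timepoint_tissue()
        out = planted_shift_simulation(cells, "closest", fraction=0.0, seed=0)
        assert out.cell_type.equals(cells.cell_type)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            planted_shift_simulation(_two_timepoint_tissue(), "nearest")

    def test_closest_mode_creates_near_leukemia_queries(self):
        cells = _two_timepoint_tissue()
        out = planted_shift_simulation(cells, "closest", query_type="planted-T", seed=0)
        s = min_distance_sample(
            out[(out.timepoint == "A")], "planted-T"
        )
        assert s.usable
        assert np.median(s.values) < 5.0

    def test_positive_control_detected(self):
        """Furthest-at-A / closest-at-B planting: the observed shift is
        negative and flagged below 5 µm (single seeded run; the power sweep
        lives in the acceptance suite)."""
        cells = _two_timepoint_tissue(seed=3)
        a = planted_shift_simulation(
            cells[cells.timepoint == "A"], "furthest", query_type="planted-T", seed=1
        )
        b = planted_shift_simulation(
            cells[cells.timepoint == "B"], "closest", query_type="planted-T", seed=2
        )
        merged = pd.concat([a, b], ignore_index=True)
        res = density_shift_test(merged, "planted-T", j=50, seed=9)
        near = res.grid < 5
        assert ((res.shift < 0) & res.flags & near).any()


class TestEndToEnd:
    def test_deterministic_given_seed(self):
        cells = _two_timepoint_tissue(seed=5)
        r1 = density_shift_test(cells, "T CD8", j=20, seed=11)
        r2 = density_shift_test(cells, "T CD8", j=20, seed=11)
        assert np.array_equal(r1.shift, r2.shift)
        assert np.array_equal(r1.flags, r2.flags)

    def test_null_flag_rate_moderate(self):
        """Null tissue: the lenient 1-SD rule flags ~32% of grid points on
        average (whole curves move in and out of the band together, so the
        per-replicate rate is dispersed; the mean over replicates is stable)."""
        rates = []
        for seed in range(30, 42):
            cells = _two_timepoint_tissue(seed=seed)
            res = density_shift_test(cells, "T CD8", j=50, seed=seed)
            rates.append(res.flags.mean())
        assert 0.15 < np.mean(rates) < 0.50
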