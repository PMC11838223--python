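"""Design construction, Laplace Poisson GLMM, contrasts, Bonferroni."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from nicheshift.glmm import (
    GlmmFit,
    adjust_bonferroni,
    build_design,
    contrast_rr,
    fit_poisson_glmm,
    later_vs_baseline_in_responders,
    responder_vs_nonresponder_at_baseline,
)
from nicheshift.synthetic import simulate_neighborhood_counts


@pytest.fixture(scope="module")
def sim_table():
    return simulate_neighborhood_counts(
        n_fovs_per_group=5, index_cells_per_fov=60, rr_b_vs_a_responders=2.5, seed=1
    )


@pytest.fixture(scope="module")
def sim_fit(sim_table):
    return fit_poisson_glmm(build_design(sim_table, "query"))


class TestBuildDesign:
    def test_full_factorial_has_twenty_columns(self, sim_table):
        frame = build_design(sim_table, "query")
        assert frame.X.shape[1] == 20  # 2 x 2 x 5 factorial with intercept
        assert "Intercept" in frame.X.columns
        assert "response[responder]:timepoint[B]:ring[4]" in frame.X.columns

    def test_offset_is_log_ring_total(self, sim_table):
        frame = build_design(sim_table, "query")
        totals = np.sort(sim_table["ring_total"].to_numpy(float))
        assert np.allclose(np.sort(np.exp(frame.offset)), totals)

    def test_zero_ring_total_dropped(self, sim_table):
        t = sim_table.copy()
        t.loc[t.index[0], "ring_total"] = 0
        frame = build_design(t, "query")
        assert frame.n_dropped_zero_total == 1
        assert len(frame.y) == len(sim_table) - 1

    def test_absent_type_gives_all_zero_counts(self, sim_table):
        frame = build_design(sim_table, "no-such-type")
        assert frame.y.sum() == 0
        assert len(frame.y) == len(sim_table)

    def test_single_level_factor_reduces_design(self, sim_table):
        t = sim_table[sim_table.response == "responder"]
        frame = build_design(t, "query")
        assert not any(c.startswith("response") for c in frame.X.columns)

    def test_timepoint_restriction(self):
        tab = simulate_neighborhood_counts(
            n_fovs_per_group=2, index_cells_per_fov=5, timepoints=("A", "B"), seed=0
        )
        tab2 = tab.copy()
        tab2["timepoint"] = tab2["timepoint"].map({"A": "A", "B": "C"})
        full = pd.concat([tab, tab2], ignore_index=True)
        frame = build_design(full, "query", timepoints=("A", "B"))
        assert set(c for c in frame.X.columns if "timepoint[C]" in c) == set()


class TestFit:
    def test_planted_rr_recovered(self, sim_fit):
        """Planted log RR = log 2.5 for responders at B: estimate lands in
        [2.0, 3.1] at this simulation size."""
        res = contrast_rr(sim_fit, later_vs_baseline_in_responders(sim_fit, ring=None))
        assert 2.0 < res.rate_ratio < 3.1

    def test_offset_invariance(self, sim_table):
        """Doubling every ring_total (holding counts) shifts the intercept
        but leaves contrast estimates essentially unchanged."""
        fit1 = fit_poisson_glmm(build_design(sim_table, "query"))
        t2 = sim_table.copy()
        t2["ring_total"] = 2 * t2["ring_total"]
        fit2 = fit_poisson_glmm(build_design(t2, "query"))
        c = later_vs_baseline_in_responders(fit1, ring=2)
        e1 = contrast_rr(fit1, c).estimate
        e2 = contrast_rr(fit2, c).estimate
        assert abs(e1 - e2) < 1e-2
        assert fit2.params["Intercept"] == pytest.approx(
            fit1.params["Intercept"] - np.log(2), abs=1e-2
        )

    def test_needs_two_fovs(self, sim_table):
        t = sim_table[sim_table.fov_id == "F001"]
        with pytest.raises(ValueError):
            fit_poisson_glmm(build_design(t, "query"))

    def test_null_estimates_within_two_se(self):
        """Null simulations: the B-vs-A responder contrast stays within 2 SE
        of zero in >= 90% of replicates."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            tab = simulate_neighborhood_counts(
                n_fovs_per_group=5, index_cells_per_fov=20,
                rr_b_vs_a_responders=1.0, seed=1000 + rep,
            )
            fit = fit_poisson_glmm(build_design(tab, "query"))
            res = contrast_rr(fit, later_vs_baseline_in_responders(fit, ring=None))
            if abs(res.estimate) < 2 * res.se:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4::glmer on the same design agrees on
        fixed effects and the variance component."""
        tab = simulate_neighborhood_counts(
            n_fovs_per_group=4, index_cells_per_fov=30, rr_b_vs_a_responders=2.0, seed=3
        )
        frame = build_design(tab, "query")
        fit = fit_poisson_glmm(frame)
        df = frame.X.copy()
        df["y"] = frame.y
        df["off"] = frame.offset
        df["fov"] = np.array(frame.group_labels)[frame.group_codes]
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "r.csv"
        rscript = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}", check.names=FALSE)
        xcols <- setdiff(colnames(d), c("y","off","fov","Intercept"))
        f <- as.formula(paste("y ~", paste(sprintf("`%s`", xcols), collapse="+"), "+ (1|fov)"))
        m <- glmer(f, data=d, family=poisson, offset=d$off)
        v <- as.data.frame(VarCorr(m))$vcov[1]
        write.csv(data.frame(name=c(names(fixef(m)), ".sig2"), est=c(fixef(m), v)),
                  "{out}", row.names=FALSE)
        """
        r = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out)
        ref["name"] = (
            ref["name"].str.replace("`", "", regex=False)
            .str.replace("(Intercept)", "Intercept", regex=False)
        )
        ref = ref.set_index("name")["est"]
        for name in fit.params.index:
            assert fit.params[name] == pytest.approx(ref[name], abs=0.02)
        assert fit.re_var == pytest.approx(ref[".sig2"], rel=0.1, abs=0.01)


class TestContrasts:
    def test_single_coefficient_rr(self, sim_fit):
        name = "timepoint[B]"
        res = contrast_rr(sim_fit, {name: 1.0})
        assert res.rate_ratio == pytest.approx(np.exp(sim_fit.params[name]))
        # and the textbook value: beta = 0.9163 -> RR 2.5003
        assert np.exp(0.9163) == pytest.approx(2.5003, abs=5e-4)

    def test_zero_vector_raises(self, sim_fit):
        with pytest.raises(ValueError):
            contrast_rr(sim_fit, {"timepoint[B]": 0.0})

    def test_unknown_name_raises(self, sim_fit):
        with pytest.raises(KeyError):
            contrast_rr(sim_fit, {"nonexistent": 1.0})

    def test_builders_match_manual_sums(self, sim_fit):
        p = sim_fit.params
        res = contrast_rr(sim_fit, later_vs_baseline_in_responders(sim_fit, ring=2))
        manual = (
            p["timepoint[B]"]
            + p["response[responder]:timepoint[B]"]
            + p["timepoint[B]:ring[2]"]
            + p["response[responder]:timepoint[B]:ring[2]"]
        )
        assert res.estimate == pytest.approx(manual)
        res2 = contrast_rr(sim_fit, responder_vs_nonresponder_at_baseline(sim_fit, ring=1))
        manual2 = p["response[responder]"] + p["response[responder]:ring[1]"]
        assert res2.estimate == pytest.approx(manual2)

    def test_nonconverged_fit_refused(self, sim_fit):
        bad = GlmmFit(
            cell_type="x", params=sim_fit.params, cov=sim_fit.cov, re_var=0.1,
            re_modes=np.zeros(2), converged=False, n_rows=10, loglike=0.0,
            levels=sim_fit.levels,
        )
        with pytest.raises(ValueError):
            contrast_rr(bad, {"timepoint[B]": 1.0})


class TestBonferroni:
    @pytest.mark.parametrize("raw,m,expected", [(0.01, 5, 0.05), (0.4, 10, 1.0), (0.03, 1, 0.03)])
    def test_adjustment(self, raw, m, expected):
        results = [_dummy_result(raw)]
        adjust_bonferroni(results, m=m)
        assert results[0].p_adj == pytest.approx(expected)

    def test_default_m_is_len(self):
        results = [_dummy_result(0.01), _dummy_result(0.02)]
        adjust_bonferroni(results)
        assert results[0].p_adj == pytest.approx(0.02)
        assert results[1].p_adj == pytest.approx(0.04)
        assert all(r.p_adj >= r.p_raw for r in results)


def _dummy_result(p):
    from nicheshift.glmm import ContrastResult

    return ContrastResult(
        cell_type="t", contrast="c", estimate=0.1, se=0.05,
        rate_ratio=1.1, ci_low=1.0, ci_high=1.2, p_raw=p,
    )
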