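"""Poisson mixed models for leukemia-neighbourhood composition.

One model is fitted per cell type: the count of that type in each ring
around each index (leukemia) cell is the response, the full three-way
interaction of patient response (responder/nonresponder), timepoint and
ring is the fixed-effect design, the log of the ring's total cell count is
an offset, and each FOV gets a random intercept.  Contrasts of interest —
"responders, later vs baseline timepoint within a ring" and "responder vs
nonresponder at baseline within a ring" — are reported as rate ratios
(exponentiated contrast estimates) with Wald tests and Bonferroni-adjusted
p-values across all models fitted.

The marginal likelihood is maximised by a Laplace approximation: for a
candidate random-intercept variance the fixed effects and the per-FOV
intercepts are jointly maximised by Newton iterations on the penalised
Poisson log-likelihood, and the variance itself by a bounded 1-D search on
the Laplace objective.  Fixed-effect covariances come from the inverse of
the joint Hessian at the optimum (the same conditional Wald covariance
lme4 reports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Design construction


@dataclass
class ModelFrame:
    """Design for one cell type's neighbourhood model."""

    y: np.ndarray
    X: pd.DataFrame  # includes the intercept column
    offset: np.ndarray
    group_codes: np.ndarray
    group_labels: list
    cell_type: str
    levels: dict
    n_dropped_zero_total: int = 0
    #: FOVs per (response, timepoint) cell, for containment-df t tests
    fovs_per_cell: dict = field(default_factory=dict)


def _interaction_columns(frame: pd.DataFrame, levels: dict) -> pd.DataFrame:
    """Treatment-coded full factorial expansion response × timepoint × ring."""
    cols = {"Intercept": np.ones(len(frame))}
    ind = {}
    for fac, lv in levels.items():
        for level in lv[1:]:
            name = f"{fac}[{level}]"
            ind[name] = (frame[fac] == level).to_numpy(float)
    # main effects
    cols.update(ind)
    names = {fac: [f"{fac}[{l}]" for l in lv[1:]] for fac, lv in levels.items()}
    fac_order = list(levels)
    # two-way and three-way products
    for i in range(len(fac_order)):
        for j in range(i + 1, len(fac_order)):
            for a in names[fac_order[i]]:
                for b in names[fac_order[j]]:
                    cols[f"{a}:{b}"] = cols[a] * cols[b]
    if len(fac_order) == 3:
        for a in names[fac_order[0]]:
            for b in names[fac_order[1]]:
                for c in names[fac_order[2]]:
                    cols[f"{a}:{b}:{c}"] = cols[a] * cols[b] * cols[c]
    return pd.DataFrame(cols, index=frame.index)


def build_design(
    table: pd.DataFrame,
    cell_type: str,
    timepoints: tuple[str, str] | None = None,
) -> ModelFrame:
    """Build the model frame for one cell type from a neighbourhood count
    table (sparse long format from :func:`nicheshift.geometry.neighborhood_counts`).

    The grid of (index cell × ring) is completed with zero counts for rings
    where the target type was absent but other neighbours were present;
    rings with ``ring_total`` 0 carry no information under the offset model
    and are dropped (logged).  Reference levels: nonresponder, the earliest
    timepoint, ring 0.

    ``timepoints`` optionally restricts the frame to the pair under
    comparison (baseline vs post-treatment).
    """
    if len(table) == 0:
        raise ValueError("empty neighbourhood count table")
    t = table.copy()
    if timepoints is not None:
        t = t[t["timepoint"].isin(timepoints)]
        if len(t) == 0:
            raise ValueError(f"no rows at timepoints {timepoints}")
    key = ["index_cell_id", "fov_id", "ring_index", "patient_id", "timepoint", "response"]
    totals = t.groupby(key, sort=True)["ring_total"].first().reset_index()
    target = (
        t[t["cell_type"] == cell_type]
        .groupby(key, sort=True)["count"]
        .sum()
        .reset_index()
    )
    frame = totals.merge(target, on=key, how="left")
    frame["count"] = frame["count"].fillna(0).astype(int)
    n_zero = int((frame["ring_total"] == 0).sum())
    if n_zero:
        logger.info("build_design: dropping %d rows with ring_total=0", n_zero)
        frame = frame[frame["ring_total"] > 0]
    frame = frame.reset_index(drop=True)

    levels = {}
    resp = sorted(frame["response"].unique(), key=lambda r: (r != "nonresponder", r))
    tps = sorted(frame["timepoint"].unique())
    rings = sorted(frame["ring_index"].unique())
    for fac, lv in (("response", resp), ("timepoint", tps), ("ring", rings)):
        if len(lv) < 2:
            logger.warning("build_design: factor %s has a single level %s; reduced design", fac, lv)
        levels[fac] = lv
    frame["ring"] = frame["ring_index"]
    levels = {f: lv for f, lv in levels.items() if len(lv) > 1}
    X = _interaction_columns(frame, levels)
    group_labels, group_codes = np.unique(frame["fov_id"], return_inverse=True)
    fovs_per_cell = (
        frame.groupby(["response", "timepoint"], observed=True)["fov_id"].nunique().to_dict()
    )
    return ModelFrame(
        y=frame["count"].to_numpy(float),
        X=X,
        offset=np.log(frame["ring_total"].to_numpy(float)),
        group_codes=group_codes,
        group_labels=list(group_labels),
        cell_type=cell_type,
        levels=levels,
        n_dropped_zero_total=n_zero,
        fovs_per_cell=fovs_per_cell,
    )


# ---------------------------------------------------------------------------
# Laplace-approximated Poisson GLMM


@dataclass
class GlmmFit:
    """Fitted Poisson mixed model for one cell type."""

    cell_type: str
    params: pd.Series
    cov: pd.DataFrame
    re_var: float
    re_modes: np.ndarray
    converged: bool
    n_rows: int
    loglike: float
    levels: dict = field(default_factory=dict)
    fovs_per_cell: dict = field(default_factory=dict)


def _joint_mode(y, X, offset, g, G, sig2, beta, u, max_iter=100, tol=1e-9):
    """Newton maximisation of the penalised Poisson log-likelihood over
    (fixed effects, random intercepts) at fixed variance ``sig2``."""
    p = X.shape[1]

    def pen_ll(beta, u):
        eta = np.clip(X @ beta + offset + u[g], -30, 30)
        return float(np.sum(y * eta - np.exp(eta)) - 0.5 * np.sum(u**2) / sig2)

    cur = pen_ll(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset + u[g], -30, 30)
        mu = np.exp(eta)
        r = y - mu
        grad = np.concatenate([X.T @ r, np.bincount(g, r, G) - u / sig2])
        Hbb = (X.T * mu) @ X
        Hbu = np.zeros((G, p))
        np.add.at(Hbu, g, mu[:, None] * X)
        duu = np.bincount(g, mu, G) + 1.0 / sig2
        H = np.zeros((p + G, p + G))
        H[:p, :p] = Hbb
        H[:p, p:] = Hbu.T
        H[p:, :p] = Hbu
        H[p:, p:] = np.diag(duu)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p + G), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            nb, nu = beta + t * step[:p], u + t * step[p:]
            new = pen_ll(nb, nu)
            if new >= cur - 1e-12:
                break
            t /= 2
        beta, u, improved = nb, nu, new - cur
        cur = new
        if np.max(np.abs(grad)) < tol or abs(improved) < 1e-10:
            converged = True
            break
    return beta, u, cur, converged


def _laplace_objective(y, X, offset, g, G, sig2, state):
    beta, u, pen, ok = _joint_mode(y, X, offset, g, G, sig2, state["beta"], state["u"])
    state["beta"], state["u"], state["ok"] = beta, u, ok
    eta = np.clip(X @ beta + offset + u[g], -30, 30)
    mu = np.exp(eta)
    Hg = np.bincount(g, mu, G)
    ll = (
        np.sum(y * eta - mu - special.gammaln(y + 1))
        - 0.5 * np.sum(u**2) / sig2
        - 0.5 * np.sum(np.log(sig2 * Hg + 1.0))
    )
    return float(ll)


def fit_poisson_glmm(frame: ModelFrame) -> GlmmFit:
    """Fit the Poisson random-intercept model by Laplace approximation.

    Requires at least two FOVs.  Start values come from an unpenalised
    Poisson GLM (random intercepts at zero).
    """
    y, offset, g = frame.y, frame.offset, frame.group_codes
    X = frame.X.to_numpy(float)
    names = list(frame.X.columns)
    G = len(frame.group_labels)
    if G < 2:
        raise ValueError("need at least 2 FOVs to estimate a FOV random intercept")
    p = X.shape[1]
    # Poisson GLM start for the fixed effects
    import statsmodels.api as sm

    try:
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = np.asarray(glm.params)
    except Exception:  # ill-conditioned start; fall back to intercept-only
        beta0 = np.zeros(p)
        with np.errstate(divide="ignore"):
            beta0[0] = np.log(max(y.mean(), 1e-8)) - offset.mean()
    state = {"beta": beta0, "u": np.zeros(G), "ok": False}

    def neg(log_sig2):
        return -_laplace_objective(y, X, offset, g, G, np.exp(log_sig2), state)

    res = optimize.minimize_scalar(neg, bounds=(-10.0, 3.0), method="bounded",
                                   options={"xatol": 1e-4})
    sig2 = float(np.exp(res.x))
    ll = -float(res.fun)
    beta, u = state["beta"], state["u"]
    # conditional covariance of the fixed effects from the joint Hessian
    eta = np.clip(X @ beta + offset + u[g], -30, 30)
    mu = np.exp(eta)
    Hbb = (X.T * mu) @ X
    Hbu = np.zeros((G, p))
    np.add.at(Hbu, g, mu[:, None] * X)
    duu = np.bincount(g, mu, G) + 1.0 / sig2
    cov_beta = np.linalg.inv(Hbb - Hbu.T @ (Hbu / duu[:, None]))
    converged = bool(state["ok"]) and res.success
    if not converged:
        logger.warning("fit_poisson_glmm: %s did not converge", frame.cell_type)
    return GlmmFit(
        cell_type=frame.cell_type,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        re_var=sig2,
        re_modes=u,
        converged=converged,
        n_rows=len(y),
        loglike=ll,
        levels=frame.levels,
        fovs_per_cell=frame.fovs_per_cell,
    )


# ---------------------------------------------------------------------------
# Contrasts


@dataclass
class ContrastResult:
    cell_type: str
    contrast: str
    estimate: float
    se: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adj: float | None = None

    def as_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "contrast": self.contrast,
            "estimate": self.estimate,
            "se": self.se,
            "rate_ratio": self.rate_ratio,
            "CI_low": self.ci_low,
            "CI_high": self.ci_high,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
        }


def _containment_df(fit: GlmmFit, c: pd.Series) -> float:
    """Containment denominator df for a contrast: the number of FOVs lying in
    the response×timepoint cells the contrast actually compares, minus the
    number of such cells.  FOV-level comparisons at few FOVs then use a t
    reference instead of the anti-conservative normal."""
    if not fit.fovs_per_cell or "response" not in fit.levels or "timepoint" not in fit.levels:
        return np.inf
    rings = fit.levels.get("ring", [None])
    combos = []
    rows = []
    for resp in fit.levels["response"]:
        for tp in fit.levels["timepoint"]:
            for ring in rings:
                frame = pd.DataFrame({"response": [resp], "timepoint": [tp], "ring": [ring]})
                rows.append(_interaction_columns(frame, fit.levels).iloc[0])
                combos.append((resp, tp))
    Xc = pd.DataFrame(rows)[fit.params.index].to_numpy(float)
    # weights on cell-ring means reproducing the contrast: w = (Xc^T)^+ c
    w, *_ = np.linalg.lstsq(Xc.T, c.to_numpy(), rcond=None)
    cell_w: dict = {}
    for (cell, wi) in zip(combos, w):
        cell_w[cell] = cell_w.get(cell, 0.0) + abs(wi)
    involved = [cell for cell, wi in cell_w.items() if wi > 1e-8]
    n_fovs = sum(fit.fovs_per_cell.get(cell, 0) for cell in involved)
    if n_fovs <= len(involved):
        return np.inf
    return float(n_fovs - len(involved))


def contrast_rr(fit: GlmmFit, contrast: dict[str, float], name: str | None = None) -> ContrastResult:
    """Test of a named linear combination of coefficients, reported as a
    rate ratio with a 95% CI (t reference with containment df)."""
    if not fit.converged:
        raise ValueError("refusing to compute contrasts on a non-converged fit")
    if not contrast or all(v == 0 for v in contrast.values()):
        raise ValueError("zero contrast vector")
    missing = set(contrast) - set(fit.params.index)
    if missing:
        raise KeyError(f"contrast names not in model: {sorted(missing)}")
    c = pd.Series(0.0, index=fit.params.index)
    for k, v in contrast.items():
        c[k] = v
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov @ c))
    z = est / se if se > 0 else np.inf
    ddf = _containment_df(fit, c)
    if np.isfinite(ddf) and ddf > 0:
        p = float(2 * stats.t.sf(abs(z), ddf))
        crit = float(stats.t.ppf(0.975, ddf))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
        crit = 1.959963984540054
    half = crit * se
    return ContrastResult(
        cell_type=fit.cell_type,
        contrast=name or "+".join(f"{v:g}*{k}" for k, v in contrast.items()),
        estimate=est,
        se=se,
        rate_ratio=float(np.exp(est)),
        ci_low=float(np.exp(est - half)),
        ci_high=float(np.exp(est + half)),
        p_raw=p,
    )


def _ring_terms(base_terms: list[str], ring, levels: dict) -> dict[str, float]:
    out = {t: 1.0 for t in base_terms}
    rings = levels.get("ring", [])
    if ring is not None and rings and ring != rings[0]:
        for t in base_terms:
            out[f"{t}:ring[{ring}]"] = 1.0
    return out


def later_vs_baseline_in_responders(fit_or_levels, ring=None) -> dict[str, float]:
    """log-RR of the later vs earlier timepoint among responders in ``ring``
    (``ring=None``: the reference ring)."""
    levels = fit_or_levels.levels if isinstance(fit_or_levels, GlmmFit) else fit_or_levels
    tp = levels["timepoint"][1]
    resp = levels["response"][1]
    return _ring_terms([f"timepoint[{tp}]", f"response[{resp}]:timepoint[{tp}]"], ring, levels)


def responder_vs_nonresponder_at_baseline(fit_or_levels, ring=None) -> dict[str, float]:
    """log-RR responder vs nonresponder at the baseline timepoint in ``ring``."""
    levels = fit_or_levels.levels if isinstance(fit_or_levels, GlmmFit) else fit_or_levels
    resp = levels["response"][1]
    return _ring_terms([f"response[{resp}]"], ring, levels)


def average_over_rings(builder, fit: GlmmFit) -> dict[str, float]:
    """Ring-averaged version of a per-ring contrast builder."""
    rings = fit.levels.get("ring", [None])
    acc: dict[str, float] = {}
    for r in rings:
        for k, v in builder(fit, r).items():
            acc[k] = acc.get(k, 0.0) + v / len(rings)
    return acc


def adjust_bonferroni(results: list[ContrastResult], m: int | None = None) -> list[ContrastResult]:
    """Bonferroni adjustment over all models/contrasts fitted (in place)."""
    if not results:
        return results
    m = m if m is not None else len(results)
    if m < 1:
        raise ValueError("m must be >= 1")
    for r in results:
        r.p_adj = min(1.0, m * r.p_raw)
    return results


def fit_all_cell_types(
    table: pd.DataFrame,
    cell_types: list[str] | None = None,
    timepoints: tuple[str, str] | None = None,
    contrast_builders: dict | None = None,
    per_ring: bool = True,
) -> pd.DataFrame:
    """Fit one model per cell type and emit tidy per-ring contrast results
    with Bonferroni adjustment across everything fitted."""
    if cell_types is None:
        cell_types = sorted(table["cell_type"].unique())
    if contrast_builders is None:
        contrast_builders = {
            "later_vs_baseline_responders": later_vs_baseline_in_responders,
            "responder_vs_nonresponder_baseline": responder_vs_nonresponder_at_baseline,
        }
    results: list[ContrastResult] = []
    rows = []
    for ct in cell_types:
        try:
            frame = build_design(table, ct, timepoints=timepoints)
            fit = fit_poisson_glmm(frame)
        except ValueError as e:
            logger.warning("skipping %s: %s", ct, e)
            continue
        rings = fit.levels.get("ring", [None]) if per_ring else [None]
        for cname, builder in contrast_builders.items():
            for ring in rings:
                try:
                    vec = builder(fit, ring)
                    res = contrast_rr(fit, vec, name=cname)
                except (KeyError, ValueError) as e:
                    logger.warning("contrast %s ring %s failed for %s: %s", cname, ring, ct, e)
                    continue
                rows.append((res, ring))
                results.append(res)
    adjust_bonferroni(results)
    return pd.DataFrame(
        [{**r.as_dict(), "ring": ring} for r, ring in rows]
    )
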