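"""Proximity-stratified pseudo-bulk ligand–receptor analysis.

Read depth per cell is too low for single-cell ligand–receptor scoring, so
expression is aggregated per FOV: cells of each type are split by distance
to the nearest leukemia cell into a close group (<= 5 µm) and a far group
(>= 30 µm; the band in between is excluded), and mean counts per gene are
computed per (FOV, cell type, group).  Anchor genes — ligands (or
receptors) highly expressed by leukemia cells, i.e. whose per-FOV leukemia
median exceeds the mean of the other cell types' medians by two of their
standard deviations — select the pairs to test; for each such pair the
partner gene is compared between the close and far groups of every other
cell type with a Mann–Whitney U test using FOVs as replicates, and
Benjamini–Hochberg adjusted p-values are reported per sample and
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .geometry import nearest_type_distances

logger = logging.getLogger(__name__)

CLOSE_UM = 5.0
FAR_UM = 30.0


def load_lr_pairs(path=None) -> pd.DataFrame:
    """Two-column ligand/receptor gene-symbol table (TSV).

    Without a path, loads the packaged 25-pair fixture (CellTalkDB-style,
    including TNFSF12/TNFRSF12A, the TWEAK/TWEAKR pair).
    """
    if path is None:
        path = resources.files("nicheshift.data") / "lr_pairs.tsv"
    pairs = pd.read_csv(path, sep="\t")
    pairs.columns = [c.strip().lower() for c in pairs.columns]
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError("LR pair table needs 'ligand' and 'receptor' columns")
    pairs["ligand"] = pairs["ligand"].str.upper().str.strip()
    pairs["receptor"] = pairs["receptor"].str.upper().str.strip()
    pairs = pairs.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)
    return pairs[["ligand", "receptor"]]


def assign_proximity_groups(
    cells: pd.DataFrame,
    close_um: float = CLOSE_UM,
    far_um: float = FAR_UM,
    ref_type: str = "leukemia",
) -> pd.DataFrame:
    """Distance to nearest leukemia cell and close/far/neither group label
    for every non-leukemia cell (thresholds inclusive on both sides)."""
    d = nearest_type_distances(cells, ref_type)
    group = np.where(
        d["dist_um"] <= close_um, "close", np.where(d["dist_um"] >= far_um, "far", "neither")
    )
    return d.assign(group=group)


def pseudobulk(
    counts: pd.DataFrame,
    cells: pd.DataFrame,
    genes: list[str],
    extra_keys: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mean raw counts per gene within each (FOV, cell type[, extra]) group."""
    genes = [g for g in genes if g in counts.columns]
    keys = ["fov_id", "cell_type", *extra_keys]
    joined = cells[["cell_id", *keys]].merge(
        counts[genes], left_on="cell_id", right_index=True
    )
    agg = joined.groupby(keys, sort=True)[genes].mean()
    agg["n_cells"] = joined.groupby(keys, sort=True).size()
    return agg.reset_index()


def leukemia_high_genes(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    genes: list[str],
    leukemia_type: str = "leukemia",
    k_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-FOV flags for genes highly expressed by leukemia cells.

    Within each FOV the per-cell-type median expression of each gene is
    computed; a gene is flagged when the leukemia median exceeds the mean of
    the other types' medians by ``k_sd`` sample standard deviations (of
    those medians).  FOVs with fewer than 3 non-leukemia cell types are
    skipped.
    """
    genes = [g for g in genes if g in counts.columns]
    joined = cells[["cell_id", "fov_id", "cell_type"]].merge(
        counts[genes], left_on="cell_id", right_index=True
    )
    med = joined.groupby(["fov_id", "cell_type"], sort=True)[genes].median()
    rows = []
    for fov, sub in med.groupby(level="fov_id"):
        sub = sub.droplevel("fov_id")
        if leukemia_type not in sub.index:
            continue
        others = sub.drop(index=leukemia_type)
        if len(others) < 3:
            logger.info("leukemia_high_genes: FOV %s has <3 other cell types; skipped", fov)
            continue
        leu = sub.loc[leukemia_type]
        mu = others.mean(axis=0)
        sd = others.std(axis=0, ddof=1)
        zero_sd = (sd == 0) & (leu > mu)
        if zero_sd.any():
            logger.info(
                "leukemia_high_genes: FOV %s genes %s flagged with zero spread among other types",
                fov, list(leu.index[zero_sd]),
            )
        flagged = leu > mu + k_sd * sd
        rows.append(
            pd.DataFrame({"fov_id": fov, "gene": genes, "flagged": flagged.to_numpy()})
        )
    if not rows:
        return pd.DataFrame(columns=["fov_id", "gene", "flagged"])
    return pd.concat(rows, ignore_index=True)


def mann_whitney_close_far(close_means, far_means) -> tuple[float, float]:
    """Two-sided Mann–Whitney U of per-FOV close vs far mean expression.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise.  Returns (U of the close group, p).
    """
    close_means = np.asarray(close_means, dtype=float)
    far_means = np.asarray(far_means, dtype=float)
    if len(close_means) == 0 or len(far_means) == 0:
        raise ValueError("empty group")
    res = mannwhitneyu(close_means, far_means, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def run_lr_analysis(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    pairs: pd.DataFrame,
    direction: str = "ligand-on-leukemia",
    close_um: float = CLOSE_UM,
    far_um: float = FAR_UM,
    k_sd: float = 2.0,
    anchor_persistence: float = 0.5,
    min_fovs_per_group: int = 2,
    leukemia_type: str = "leukemia",
    adjust_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Proximity-stratified LR testing for every (patient, timepoint) sample.

    ``direction`` anchors either the ligand or the receptor list on leukemia
    cells; anchor genes must pass the 2-SD leukemia-high rule in at least
    ``anchor_persistence`` of the sample's FOVs.  For each surviving pair
    the partner gene is tested close vs far per non-leukemia cell type
    (per-FOV pseudo-bulk means as replicates); p-values are adjusted within
    sample × direction.
    """
    if direction not in ("ligand-on-leukemia", "receptor-on-leukemia"):
        raise ValueError("direction must be 'ligand-on-leukemia' or 'receptor-on-leukemia'")
    if len(pairs) == 0:
        return _empty_lr_result()
    anchor_col, partner_col = (
        ("ligand", "receptor") if direction == "ligand-on-leukemia" else ("receptor", "ligand")
    )
    results = []
    for (patient, tp), sample_cells in cells.groupby(["patient_id", "timepoint"], sort=True):
        genes = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
        flags = leukemia_high_genes(sample_cells, counts, genes, leukemia_type, k_sd)
        if len(flags) == 0:
            continue
        frac = flags.groupby("gene")["flagged"].mean()
        anchors = set(frac[frac >= anchor_persistence].index)
        use = pairs[pairs[anchor_col].isin(anchors)]
        if len(use) == 0:
            continue
        prox = assign_proximity_groups(sample_cells, close_um, far_um, leukemia_type)
        grouped = sample_cells.merge(prox[["cell_id", "group"]], on="cell_id", how="inner")
        grouped = grouped[grouped["group"].isin(["close", "far"])]
        partner_genes = sorted(set(use[partner_col]) & set(counts.columns))
        if not partner_genes or len(grouped) == 0:
            continue
        pb = pseudobulk(counts, grouped, partner_genes, extra_keys=("group",))
        for _, pair in use.iterrows():
            gene = pair[partner_col]
            if gene not in partner_genes:
                continue
            for ctype, sub in pb.groupby("cell_type"):
                if ctype == leukemia_type:
                    continue
                close = sub.loc[sub["group"] == "close", gene].to_numpy()
                far = sub.loc[sub["group"] == "far", gene].to_numpy()
                if len(close) < min_fovs_per_group or len(far) < min_fovs_per_group:
                    logger.debug(
                        "skipping %s/%s/%s: close %d, far %d FOVs",
                        patient, ctype, gene, len(close), len(far),
                    )
                    continue
                u, p = mann_whitney_close_far(close, far)
                results.append(
                    {
                        "patient_id": patient,
                        "timepoint": tp,
                        "cell_type": ctype,
                        "anchor_gene": pair[anchor_col],
                        "partner_gene": gene,
                        "direction": direction,
                        "n_close_fovs": len(close),
                        "n_far_fovs": len(far),
                        "close_mean": float(close.mean()),
                        "far_mean": float(far.mean()),
                        "U": u,
                        "p_raw": p,
                    }
                )
    if not results:
        return _empty_lr_result()
    out = pd.DataFrame(results)
    out["p_adj"] = np.nan
    for (_, _), idx in out.groupby(["patient_id", "timepoint"]).groups.items():
        out.loc[idx, "p_adj"] = multipletests(out.loc[idx, "p_raw"], method=adjust_method)[1]
    return out


def _empty_lr_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "patient_id", "timepoint", "cell_type", "anchor_gene", "partner_gene",
            "direction", "n_close_fovs", "n_far_fovs", "close_mean", "far_mean",
            "U", "p_raw", "p_adj",
        ]
    )
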