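"""Reference-profile cell typing with negative-probe background adjustment.

Cell types are assigned per sample (patient-timepoint) in two rounds:

1. reference cells — cells expressing markers of exactly one cell type —
   define per-type mean expression profiles over the whole panel; every
   cell is then assigned by an independent-Poisson likelihood in which each
   gene's expected count is the cell's depth-scaled profile value plus the
   negative-probe background, and the posterior (uniform prior by default)
   picks the type;
2. cells called T or B in round 1 are re-typed the same way against
   lymphocyte subtype markers (CD4/CD8 T subsets, naive/plasma B) to
   refine the lymphocyte compartment; non-lymphocytes are never relabelled.

Large-cell sanity check: megakaryocytes are by far the largest cells, so
the fraction of cells above a size threshold (648 µm², i.e. 20,000 pixels
at 0.18 µm/px) that were typed as megakaryocytes is a useful external
validation of the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

MarkerMap = dict[str, list[str]]


def load_marker_map(path=None) -> dict[str, MarkerMap]:
    """Round-1 (broad types) and round-2 (lymphocyte subtypes) marker sets.

    Without a path, loads the packaged defaults (bone-marrow markers:
    HBB/HBA1 erythroid progenitors, PF4/PPBP megakaryocytes, CD3 genes for
    T cells, CD19/CD79A for B cells, ...).
    """
    if path is None:
        path = resources.files("nicheshift.data") / "markers.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for round_key in ("round1", "round2"):
        if round_key not in raw:
            raise ValueError(f"marker map missing '{round_key}' section")
        for t, genes in raw[round_key].items():
            if not genes:
                raise ValueError(f"marker set for {t} is empty")
    return raw


def select_reference_cells(counts: pd.DataFrame, markers: MarkerMap) -> pd.Series:
    """Cells expressing markers of exactly one type (their reference label).

    A cell is a reference for type t iff at least one of t's markers has a
    nonzero count and no marker of any other type does.  Returns a Series
    cell_id -> type covering only the reference cells.
    """
    hits = {}
    for t, genes in markers.items():
        present = [g for g in genes if g in counts.columns]
        if not present:
            logger.warning("select_reference_cells: no panel genes for type %s", t)
            continue
        hits[t] = (counts[present] > 0).any(axis=1)
    hit_frame = pd.DataFrame(hits)
    n_types = hit_frame.sum(axis=1)
    unique = n_types == 1
    labels = hit_frame.loc[unique].idxmax(axis=1)
    labels.name = "reference_type"
    return labels


@dataclass
class ReferenceProfile:
    """Mean expression per gene (rows) per cell type (columns), plus the
    dataset-wide negative-probe background mean."""

    profiles: pd.DataFrame
    negative_mean: float

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def build_reference_profiles(
    counts: pd.DataFrame,
    reference_labels: pd.Series,
    negprobe_columns: list[str],
) -> ReferenceProfile:
    """Average full-panel expression of each type's reference cells.

    The negative-control mean is the grand mean count over negative-probe
    columns over *all* cells (not just references); types without any
    reference cell are dropped with a warning.
    """
    gene_cols = [c for c in counts.columns if c not in negprobe_columns]
    cols = {}
    for t in sorted(reference_labels.unique()):
        ids = reference_labels.index[reference_labels == t]
        ids = ids.intersection(counts.index)
        if len(ids) == 0:
            logger.warning("build_reference_profiles: type %s has no reference cells; dropped", t)
            continue
        cols[t] = counts.loc[ids, gene_cols].mean(axis=0)
    if not cols:
        raise ValueError("no cell type has reference cells")
    neg = float(counts[negprobe_columns].to_numpy().mean()) if negprobe_columns else 0.0
    return ReferenceProfile(profiles=pd.DataFrame(cols), negative_mean=neg)


def poisson_type_loglik(x: np.ndarray, lam: np.ndarray, s: float, b: float) -> float:
    """Poisson log-likelihood of counts ``x`` under profile ``lam`` scaled by
    ``s`` with additive background ``b`` (constant terms in x dropped)."""
    rate = np.maximum(s * np.asarray(lam, float) + b, 1e-12)
    x = np.asarray(x, float)
    return float(np.sum(x * np.log(rate) - rate))


@dataclass
class TypingResult:
    posterior: pd.DataFrame  # cells × types
    assigned: pd.Series  # cell_id -> type
    round_label: pd.Series  # 1 or 2 per cell
    flagged_zero: list


def assign_types(
    counts: pd.DataFrame,
    profiles: ReferenceProfile,
    prior: dict[str, float] | None = None,
) -> TypingResult:
    """Posterior cell-type assignment under the scaled-Poisson likelihood.

    Each candidate type's profile is scaled so its total matches the cell's
    total count; the negative-probe mean is added per gene as nonspecific
    background.  Cells with zero counts get a uniform posterior (flagged).
    """
    prof = profiles.profiles
    genes = [g for g in prof.index if g in counts.columns]
    lam = prof.loc[genes].to_numpy()  # genes × types
    types = list(prof.columns)
    lam_tot = lam.sum(axis=0)
    if np.any(lam_tot <= 0):
        raise ValueError("profile with zero total expression")
    x = counts[genes].to_numpy(float)
    totals = x.sum(axis=1)
    b = profiles.negative_mean
    log_prior = np.log(
        np.array([prior.get(t, 1e-300) for t in types]) if prior else np.ones(len(types))
    )
    s = totals[:, None] / lam_tot[None, :]  # cells × types
    rate = s[:, None, :] * lam[None, :, :] + b  # cells × genes × types
    rate = np.maximum(rate, 1e-12)
    ll = np.einsum("cg,cgt->ct", x, np.log(rate)) - rate.sum(axis=1)
    ll = ll + log_prior[None, :]
    zero = totals == 0
    ll[zero] = 0.0
    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    posterior = pd.DataFrame(post, index=counts.index, columns=types)
    assigned = posterior.idxmax(axis=1)
    assigned[zero] = pd.NA
    flagged = list(counts.index[zero])
    if flagged:
        logger.warning("assign_types: %d cells with zero counts; uniform posterior", len(flagged))
    return TypingResult(
        posterior=posterior,
        assigned=assigned,
        round_label=pd.Series(1, index=counts.index),
        flagged_zero=flagged,
    )


def refine_lymphocytes(
    counts: pd.DataFrame,
    round1: TypingResult,
    round2_markers: MarkerMap,
    negprobe_columns: list[str],
    lymphocyte_types: tuple[str, ...] = ("T cell", "B cell"),
    prior: dict[str, float] | None = None,
) -> TypingResult:
    """Second-round subtype assignment restricted to round-1 T/B cells.

    Identical machinery — reference selection, profiles, posterior — run on
    the lymphocyte subset with subtype markers.  Other cells keep their
    round-1 label.  Returns the combined result.
    """
    lymph_ids = round1.assigned.index[round1.assigned.isin(lymphocyte_types)]
    if len(lymph_ids) == 0:
        logger.info("refine_lymphocytes: no %s cells; no-op", lymphocyte_types)
        return round1
    sub = counts.loc[lymph_ids]
    refs = select_reference_cells(sub, round2_markers)
    profiles = build_reference_profiles(sub, refs, negprobe_columns)
    second = assign_types(sub, profiles, prior)
    assigned = round1.assigned.copy()
    assigned.loc[second.assigned.index] = second.assigned
    round_label = round1.round_label.copy()
    round_label.loc[second.assigned.index] = 2
    posterior = round1.posterior.copy()
    return TypingResult(
        posterior=posterior,
        assigned=assigned,
        round_label=round_label,
        flagged_zero=sorted(set(round1.flagged_zero) | set(second.flagged_zero)),
    )


def type_cells(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    marker_map: dict[str, MarkerMap] | None = None,
    negprobe_columns: list[str] | None = None,
    rounds: int = 2,
    exclude_types: tuple[str, ...] = ("leukemia",),
) -> pd.Series:
    """Per-sample two-round typing of all cells not already identified
    (leukemia cells keep their label, as they are called by morphology and
    CD34 protein rather than transcripts)."""
    marker_map = marker_map or load_marker_map()
    if negprobe_columns is None:
        negprobe_columns = [c for c in counts.columns if c.startswith("NegPrb")]
    out = cells.set_index("cell_id")["cell_type"].copy()
    for (_, _), sample in cells.groupby(["patient_id", "timepoint"], sort=True):
        target = sample[~sample["cell_type"].isin(exclude_types)]
        sub_counts = counts.loc[target["cell_id"]]
        refs = select_reference_cells(sub_counts, marker_map["round1"])
        profiles = build_reference_profiles(sub_counts, refs, negprobe_columns)
        r1 = assign_types(sub_counts, profiles)
        result = r1
        if rounds >= 2:
            result = refine_lymphocytes(sub_counts, r1, marker_map["round2"], negprobe_columns)
        out.loc[result.assigned.index] = result.assigned
    return out


def validate_by_size(
    assigned: pd.Series,
    areas: pd.Series,
    threshold_um2: float = 648.0,
    large_type: str = "megakaryocyte",
):
    """Fraction of cells larger than the threshold that were typed as the
    large type (diagnostic only); None when no cell exceeds the threshold."""
    big = areas.index[areas > threshold_um2]
    big = big.intersection(assigned.index)
    if len(big) == 0:
        logger.info("validate_by_size: no cells above %.0f µm²", threshold_um2)
        return None
    return float((assigned.loc[big] == large_type).mean())
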