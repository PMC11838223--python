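"""Instance-mask merging and segmentation scoring.

Two concerns live here:

* combining separately segmented nuclear and membrane instance masks into a
  single mask per cell (membrane footprints where staining was visible,
  expanded nuclei where it was not), and
* scoring a predicted instance segmentation against ground truth with the
  F1-at-IOU metric: F1 = TP / (TP + (FP + FN)/2), where a predicted label is
  a true positive only if its intersection-over-union with a ground-truth
  label reaches the threshold (0.7 by default).

Masks are 2-D integer rasters: 0 is background, each positive label one
cell instance, at a default pixel edge of 0.18 µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage.segmentation import expand_labels

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 0.18


@dataclass
class LabelMask:
    """2-D instance label raster (0 = background)."""

    array: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        a = np.asarray(self.array)
        if a.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if a.min() < 0:
            raise ValueError("label mask must be nonnegative")
        self.array = a.astype(np.int64, copy=False)

    def labels(self) -> np.ndarray:
        u = np.unique(self.array)
        return u[u > 0]

    @property
    def n_cells(self) -> int:
        return len(self.labels())


def read_mask(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> LabelMask:
    return LabelMask(tifffile.imread(path), pixel_size_um)


def write_mask(path, mask: LabelMask) -> None:
    arr = mask.array
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed 16-bit range")
    tifffile.imwrite(path, arr.astype(np.uint16))


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two pixel sets (boolean arrays on one grid)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("pixel sets must live on the same grid")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both pixel sets are empty")
    inter = np.logical_and(a, b).sum()
    return float(inter / union)


@dataclass
class MatchLedger:
    """One-to-one matching between predicted and ground-truth labels.

    ``pairs`` holds every overlapping (pred, truth) label pair with its IOU;
    ``matches`` the accepted TP pairings.  TP + FN equals the number of truth
    labels and TP + FP the number of predicted labels.
    """

    pairs: pd.DataFrame
    matches: pd.DataFrame
    tp: int
    fp: int
    fn: int
    iou_threshold: float

    def counts(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn}


def match_masks(pred: LabelMask, truth: LabelMask, iou_threshold: float = 0.7) -> MatchLedger:
    """Greedy one-to-one matching of predicted to truth labels by IOU.

    Overlapping pairs are considered in order of descending IOU (ties broken
    by lower label ids); a pair is a true positive when both labels are still
    unmatched and its IOU >= ``iou_threshold``.  Remaining predictions are
    false positives, remaining truth labels false negatives.
    """
    p, t = pred.array, truth.array
    if p.shape != t.shape:
        raise ValueError("prediction and truth masks differ in shape")
    both = (p > 0) & (t > 0)
    pair_idx, inter = np.unique(
        np.stack([p[both], t[both]]), axis=1, return_counts=True
    ) if both.any() else (np.empty((2, 0), dtype=int), np.empty(0, dtype=int))
    p_areas = dict(zip(*np.unique(p[p > 0], return_counts=True)))
    t_areas = dict(zip(*np.unique(t[t > 0], return_counts=True)))
    pl, tl = pair_idx
    union = np.array([p_areas[a] + t_areas[b] for a, b in zip(pl, tl)]) - inter
    iou = inter / union if len(inter) else np.empty(0)
    pairs = pd.DataFrame({"pred_label": pl, "truth_label": tl, "iou": iou})
    order = pairs.sort_values(
        ["iou", "pred_label", "truth_label"], ascending=[False, True, True]
    )
    used_p: set = set()
    used_t: set = set()
    rows = []
    for r in order.itertuples(index=False):
        if r.iou < iou_threshold:
            break
        if r.pred_label in used_p or r.truth_label in used_t:
            continue
        used_p.add(r.pred_label)
        used_t.add(r.truth_label)
        rows.append(r)
    matches = pd.DataFrame(rows, columns=["pred_label", "truth_label", "iou"])
    tp = len(matches)
    fp = len(p_areas) - tp
    fn = len(t_areas) - tp
    return MatchLedger(pairs, matches, tp, fp, fn, iou_threshold)


def f1_at_iou(ledger: MatchLedger) -> float:
    """F1 = TP / (TP + (FP + FN)/2); undefined (error) when all counts are 0."""
    tp, fp, fn = ledger.tp, ledger.fp, ledger.fn
    if min(tp, fp, fn) < 0:
        raise ValueError("negative counts")
    if tp == fp == fn == 0:
        raise ValueError("F1 undefined: no predictions and no truth labels")
    return tp / (tp + (fp + fn) / 2)


def cell_areas(mask: LabelMask) -> dict[int, float]:
    """Area of each labelled cell in µm² (pixel count × pixel size²)."""
    labels, counts = np.unique(mask.array[mask.array > 0], return_counts=True)
    px_area = mask.pixel_size_um**2
    return {int(l): float(c * px_area) for l, c in zip(labels, counts)}


@dataclass
class MergeReport:
    """Bookkeeping from a nuclear/membrane merge."""

    n_membrane_cells: int = 0
    n_expanded_nuclei: int = 0
    multi_nucleus_membranes: list = field(default_factory=list)


def merge_nuclear_membrane(
    nuclei: LabelMask,
    membranes: LabelMask,
    expansion_radius_um: float = 3.0,
    return_report: bool = False,
):
    """Combine nuclear and membrane instance masks into one mask per cell.

    A nucleus whose pixels lie majority (>50%) inside one membrane label
    adopts that membrane's footprint; membranes then define one cell each
    (extra nuclei inside the same membrane are absorbed and logged).  A
    nucleus with no majority membrane is expanded by ``expansion_radius_um``
    (Euclidean, on the raster) and clipped against every already-claimed
    pixel and against competing expansions.  Membrane labels containing no
    nucleus are retained as cells.  Output labels are renumbered 1..n.
    """
    n_arr, m_arr = nuclei.array, membranes.array
    if n_arr.shape != m_arr.shape:
        raise ValueError("nuclear and membrane masks differ in shape")
    if not np.isclose(nuclei.pixel_size_um, membranes.pixel_size_um):
        raise ValueError("nuclear and membrane masks differ in pixel size")
    report = MergeReport()

    # Majority-overlap assignment of nuclei to membranes.
    nuc_labels, nuc_sizes = np.unique(n_arr[n_arr > 0], return_counts=True)
    nuc_size = dict(zip(nuc_labels, nuc_sizes))
    both = (n_arr > 0) & (m_arr > 0)
    owner: dict[int, int] = {}
    if both.any():
        pairs, counts = np.unique(np.stack([n_arr[both], m_arr[both]]), axis=1, return_counts=True)
        for (nl, ml), c in zip(pairs.T, counts):
            if c > 0.5 * nuc_size[nl]:
                owner[int(nl)] = int(ml)
    mem_to_nuclei: dict[int, list[int]] = {}
    for nl, ml in owner.items():
        mem_to_nuclei.setdefault(ml, []).append(nl)
    for ml, nls in mem_to_nuclei.items():
        if len(nls) > 1:
            report.multi_nucleus_membranes.append((ml, sorted(nls)))
            logger.info("membrane %d contains %d nuclei; merged into one cell", ml, len(nls))

    out = np.zeros_like(n_arr)
    next_label = 1
    mem_labels = np.unique(m_arr[m_arr > 0])
    mem_relabel = {}
    for ml in mem_labels:
        mem_relabel[int(ml)] = next_label
        next_label += 1
    if len(mem_labels):
        lut = np.zeros(int(m_arr.max()) + 1, dtype=np.int64)
        for ml, new in mem_relabel.items():
            lut[ml] = new
        out = lut[m_arr]
    report.n_membrane_cells = len(mem_labels)

    # Expand orphan nuclei on unclaimed pixels only.
    orphan = [int(nl) for nl in nuc_labels if int(nl) not in owner]
    report.n_expanded_nuclei = len(orphan)
    if orphan:
        orphan_raster = np.where(np.isin(n_arr, orphan), n_arr, 0)
        radius_px = expansion_radius_um / nuclei.pixel_size_um
        expanded = expand_labels(orphan_raster, distance=radius_px)
        free = out == 0
        for nl in orphan:
            sel = free & (expanded == nl)
            if sel.any():
                out[sel] = next_label
                next_label += 1
    merged = LabelMask(out, nuclei.pixel_size_um)
    return (merged, report) if return_report else merged
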