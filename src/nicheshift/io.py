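"""Reading and writing the package's table formats.

Cell tables travel as CSV with the boundary polygon serialised as WKT;
count matrices as CSV with cell_id index; transcripts as plain CSV; masks
as single-channel 16-bit TIFF (see :mod:`nicheshift.masks`); configs as
YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely import wkt

CELL_COLUMNS = [
    "cell_id", "fov_id", "patient_id", "timepoint", "response",
    "cell_type", "polygon", "area_um2", "total_counts",
]


def write_cells_csv(path, cells: pd.DataFrame) -> None:
    out = cells.copy()
    out["polygon"] = [shapely.to_wkt(p, rounding_precision=6) for p in out["polygon"]]
    out.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    cells = pd.read_csv(path, dtype={"fov_id": str, "patient_id": str, "timepoint": str})
    cells["polygon"] = cells["polygon"].map(wkt.loads)
    return cells


def write_counts_csv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, index_label="cell_id")


def read_counts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


def write_distances_csv(path, distances: pd.DataFrame) -> None:
    distances.to_csv(path, index=False)


def read_distances_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
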