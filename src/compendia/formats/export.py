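"""Raw-matrix export: TSV and HDF5.

Both carry the same matrix (keys as rows, samples as columns).  Missing
cells are "NA" in TSV and NaN in HDF5; the two exports of one matrix agree
cell-for-cell.  TSV numbers use the shortest decimal representation that
round-trips to the same float.

HDF5 layout::

    /raw/values        2-D float64, NaN = missing
    /raw/row_ids       1-D UTF-8 strings (reporter or feature keys)
    /raw/col_ids       1-D UTF-8 strings (sample names)
    /mapping/reporter_ids, /mapping/feature_ids   optional parallel arrays
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import IO, Optional

import h5py
import numpy as np
import pandas as pd

from ..model import ReporterMapping

MISSING = "NA"


def _format_value(v: float) -> str:
    if math.isnan(v):
        return MISSING
    return repr(v)  # shortest round-trippable decimal form


def write_tsv(matrix: pd.DataFrame, stream: IO[str]) -> None:
    """Write ``key\\t<sample...>`` TSV with '\\n' newlines; an empty matrix
    yields a valid header-only file."""
    stream.write("key")
    for col in matrix.columns:
        stream.write("\t" + str(col))
    stream.write("\n")
    for key, row in matrix.iterrows():
        stream.write(str(key))
        for v in row:
            stream.write("\t" + _format_value(float(v)))
        stream.write("\n")


def read_tsv_matrix(stream: IO[str]) -> pd.DataFrame:
    """Re-read a write_tsv export (inverse operation, used for round-trip
    verification)."""
    header = stream.readline().rstrip("\n")
    cols = header.split("\t")[1:]
    index: list[str] = []
    rows: list[list[float]] = []
    for line in stream:
        cells = line.rstrip("\n").split("\t")
        index.append(cells[0])
        rows.append(
            [float("nan") if c == MISSING else float(c) for c in cells[1:]]
        )
    return pd.DataFrame(rows, index=index, columns=cols, dtype=float)


def write_hdf5(
    matrix: pd.DataFrame,
    path: str | Path,
    mapping: Optional[ReporterMapping] = None,
) -> None:
    str_dtype = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        raw = f.create_group("raw")
        raw.create_dataset("values", data=matrix.to_numpy(dtype=np.float64))
        raw.create_dataset(
            "row_ids", data=np.array([str(k) for k in matrix.index], dtype=object),
            dtype=str_dtype,
        )
        raw.create_dataset(
            "col_ids", data=np.array([str(c) for c in matrix.columns], dtype=object),
            dtype=str_dtype,
        )
        if mapping is not None:
            grp = f.create_group("mapping")
            grp.create_dataset(
                "reporter_ids",
                data=np.array([r for r, _ in mapping.entries], dtype=object),
                dtype=str_dtype,
            )
            grp.create_dataset(
                "feature_ids",
                data=np.array([g for _, g in mapping.entries], dtype=object),
                dtype=str_dtype,
            )


def read_hdf5(path: str | Path) -> tuple[pd.DataFrame, Optional[list[tuple[str, str]]]]:
    """Read back an HDF5 export; returns (matrix, mapping entries or None)."""
    with h5py.File(path, "r") as f:
        values = f["raw/values"][()]
        rows = [s.decode() if isinstance(s, bytes) else s for s in f["raw/row_ids"][()]]
        cols = [s.decode() if isinstance(s, bytes) else s for s in f["raw/col_ids"][()]]
        mapping = None
        if "mapping" in f:
            rids = [s.decode() if isinstance(s, bytes) else s
                    for s in f["mapping/reporter_ids"][()]]
            fids = [s.decode() if isinstance(s, bytes) else s
                    for s in f["mapping/feature_ids"][()]]
            mapping = list(zip(rids, fids))
    values = values.reshape(len(rows), len(cols)) if values.size else np.empty((len(rows), len(cols)))
    return pd.DataFrame(values, index=rows, columns=cols, dtype=float), mapping
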