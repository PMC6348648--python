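"""Tab-delimited platform probe tables and per-sample value tables.

Both formats are plain TSV with a header row; the caller names the columns
to use (manufacturer tables differ wildly in column naming).
"""

from __future__ import annotations

import math
from typing import IO

import pandas as pd

from ..model import Measurement, Reporter, ValidationError


class TableFormatError(ValueError):
    pass


def _read_tsv(stream: IO[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError("empty table: no header row")
    return df


def _require_columns(df: pd.DataFrame, wanted: list[str]) -> None:
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"column(s) {missing} not found; available: {list(df.columns)}"
        )


def parse_probe_table(stream: IO[str], id_field: str, seq_field: str) -> list[Reporter]:
    """Read a platform probe table into Reporters.

    Rows that repeat an (id, sequence) pair exactly are collapsed to one
    reporter; the same id with a *different* sequence is an error.  Any
    remaining columns are kept as reporter metadata.
    """
    df = _read_tsv(stream)
    _require_columns(df, [id_field, seq_field])
    extra_cols = [c for c in df.columns if c not in (id_field, seq_field)]
    reporters: list[Reporter] = []
    seen: dict[str, str] = {}
    for _, row in df.iterrows():
        rid = row[id_field].strip()
        seq = row[seq_field].strip()
        if not rid:
            raise TableFormatError(f"empty probe id in column {id_field!r}")
        if rid in seen:
            if seen[rid] != seq:
                raise TableFormatError(
                    f"probe {rid!r} appears with two different sequences"
                )
            continue
        seen[rid] = seq
        meta = tuple(sorted((c, row[c]) for c in extra_cols))
        reporters.append(Reporter(id=rid, sequence=seq or None, metadata=meta))
    return reporters


def parse_value_table(stream: IO[str], id_field: str, value_field: str) -> list[Measurement]:
    """Read one sample's raw values.

    Every value cell must parse as a finite real number: missing values are
    not measurements, so "NA"/empty cells are errors rather than silently
    imputed.  Duplicate keys are errors (a sample holds at most one
    measurement per key).
    """
    df = _read_tsv(stream)
    _require_columns(df, [id_field, value_field])
    measurements: list[Measurement] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 1
        key = row[id_field].strip()
        raw = row[value_field].strip()
        if key in seen:
            raise TableFormatError(f"row {rownum}: duplicate key {key!r}")
        seen.add(key)
        try:
            value = float(raw)
        except ValueError:
            raise TableFormatError(
                f"row {rownum}: non-numeric value {raw!r} for key {key!r}"
            )
        if not math.isfinite(value):
            raise TableFormatError(f"row {rownum}: non-finite value for key {key!r}")
        try:
            measurements.append(Measurement(key=key, value=value))
        except ValidationError as exc:
            raise TableFormatError(f"row {rownum}: {exc}")
    return measurements
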