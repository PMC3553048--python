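"""Reading and writing delimited survival tables (time, status, group)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hazard import SurvivalDataset

__all__ = ["read_survival_table", "write_survival_table"]


def read_survival_table(
    path,
    time_col: str = "time",
    event_col: str = "status",
    group_col: str = "group",
    delimiter: str | None = None,
) -> SurvivalDataset:
    """Read a delimited survival table into a :class:`SurvivalDataset`.

    The file must contain a header naming the three columns (defaults:
    ``time``, ``status``, ``group``).  The delimiter is sniffed from the
    extension (.tsv -> tab, otherwise comma) unless given explicitly.
    Rows with negative times, non-binary status/group or missing cells are
    reported with their (1-based, header-excluded) row numbers.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in (time_col, event_col, group_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    sub = df[[time_col, event_col, group_col]]

    problems = []
    na_rows = sub.index[sub.isna().any(axis=1)]
    problems += [f"row {i + 1}: missing value" for i in na_rows]
    t = pd.to_numeric(sub[time_col], errors="coerce")
    bad_t = sub.index[(t < 0) | (t.isna() & sub[time_col].notna())]
    problems += [f"row {i + 1}: invalid time {sub[time_col][i]!r}" for i in bad_t]
    for name, col in ((event_col, sub[event_col]), (group_col, sub[group_col])):
        vals = pd.to_numeric(col, errors="coerce")
        bad = sub.index[(~vals.isin([0, 1])) & col.notna()]
        problems += [f"row {i + 1}: non-binary {name} value {col[i]!r}" for i in bad]
    if problems:
        raise ValueError(f"{path}: " + "; ".join(sorted(set(problems))))

    return SurvivalDataset(
        t.to_numpy(dtype=float),
        pd.to_numeric(sub[event_col]).to_numpy(dtype=np.int8),
        pd.to_numeric(sub[group_col]).to_numpy(dtype=np.int8),
    )


def write_survival_table(
    data: SurvivalDataset, path, delimiter: str | None = None
) -> None:
    """Write a dataset as a delimited table (columns time, status, group)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    data.to_dataframe().to_csv(path, sep=delimiter, index=False)
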