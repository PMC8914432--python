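"""CSV dialects and provenance sidecars used across the pipeline.

Formats (all plain CSV):

* clonogenic assays: ``cell_line,quality,dose_Gy,cells_seeded,colonies,replicate``
* survival fits:     ``cell_line,quality,a,b,c,rss_log,sf2,sf35,d10,dbar_param,dbar_auc,d0``
* expression matrix: first column ``gene``, remaining columns sample ids
* labels:            ``sample,group``
* panel:             ``cell_line,sf2,sf35,plating_efficiency,site``

Every writer drops a ``<path>.provenance.json`` sidecar recording the
command, options and seed that produced the file.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

CLONOGENIC_COLUMNS = ["cell_line", "quality", "dose_Gy", "cells_seeded", "colonies", "replicate"]
FIT_COLUMNS = [
    "cell_line", "quality", "a", "b", "c", "rss_log",
    "sf2", "sf35", "d10", "dbar_param", "dbar_auc", "d0",
]

__all__ = [
    "read_clonogenic_csv",
    "write_clonogenic_csv",
    "read_fits_csv",
    "write_fits_csv",
    "read_expression_csv",
    "write_expression_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_provenance",
]


def read_clonogenic_csv(path) -> pd.DataFrame:
    """Read and validate a clonogenic-assay table.

    Checks the header, coerces numeric columns (naming offending rows), and
    requires a dose-0 control per (cell_line, quality).
    """
    df = pd.read_csv(path)
    missing = [c for c in CLONOGENIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no records (header only)", stacklevel=2)
        return df[CLONOGENIC_COLUMNS]
    for col in ("dose_Gy", "cells_seeded", "colonies", "replicate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col!r} in rows {bad}")
        df[col] = coerced
    if (df["dose_Gy"] < 0).any() or (df["cells_seeded"] < 1).any() or (df["colonies"] < 0).any():
        raise ValueError(f"{path}: negative dose/colonies or cells_seeded < 1")
    for (line, quality), grp in df.groupby(["cell_line", "quality"]):
        if not (grp["dose_Gy"] == 0).any():
            raise ValueError(
                f"{path}: no dose-0 control for cell line {line!r} / quality {quality!r}"
            )
    return df[CLONOGENIC_COLUMNS]


def write_clonogenic_csv(df: pd.DataFrame, path, **provenance) -> None:
    df[CLONOGENIC_COLUMNS].to_csv(path, index=False)
    write_provenance(path, **provenance)


def read_fits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[FIT_COLUMNS]


def write_fits_csv(df: pd.DataFrame, path, **provenance) -> None:
    df[FIT_COLUMNS].to_csv(path, index=False)
    write_provenance(path, **provenance)


def read_expression_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_expression_csv(expr: pd.DataFrame, path, **provenance) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path)
    write_provenance(path, **provenance)


def read_labels_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    if list(df.columns) != ["sample", "group"]:
        raise ValueError(f"{path}: expected header 'sample,group', got {list(df.columns)}")
    return df.set_index("sample")["group"]


def write_labels_csv(labels: pd.Series, path, **provenance) -> None:
    labels.rename("group").rename_axis("sample").reset_index().to_csv(path, index=False)
    write_provenance(path, **provenance)


def write_provenance(path, **info) -> None:
    """JSON sidecar sufficient to re-run the producing command."""
    if not info:
        return
    sidecar = Path(str(path) + ".provenance.json")
    sidecar.write_text(json.dumps(info, indent=2, default=str) + "\n")
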