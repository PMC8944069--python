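"""OpenSim-storage (.sto/.mot) interchange and delimited-text fallbacks.

The storage dialect is a plain-text table: free-form header lines, then
``nRows=``/``nColumns=`` declarations, an ``endheader`` sentinel, a
tab-separated column-name line (time first), and the numeric body.  Reading
back a written table reproduces the values to 1e-12 (we write 17
significant digits, so round-trips are in fact exact).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StoParseError", "write_sto", "read_sto", "read_kinematics"]


class StoParseError(ValueError):
    """Malformed .sto/.mot content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def write_sto(path, table: pd.DataFrame, name: str | None = None) -> Path:
    """Write a DataFrame (first column ``time``, uniform grid) as .sto."""
    path = Path(path)
    if table.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    t = table["time"].to_numpy()
    if t.size >= 2 and not np.allclose(np.diff(t), t[1] - t[0], rtol=1e-9, atol=1e-12):
        raise ValueError("time grid must be uniform")
    n_rows, n_cols = table.shape
    lines = [
        name or path.stem,
        "version=1",
        f"nRows={n_rows}",
        f"nColumns={n_cols}",
        "inDegrees=no",
        "endheader",
        "\t".join(table.columns),
    ]
    for _, row in table.iterrows():
        lines.append("\t".join(f"{v:.17g}" for v in row.to_numpy()))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_sto(path) -> pd.DataFrame:
    """Parse a .sto/.mot file, validating the declared shape."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n_rows = n_cols = None
    header_end = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("nRows="):
            try:
                n_rows = int(s.split("=", 1)[1])
            except ValueError:
                raise StoParseError("unreadable nRows value", i + 1) from None
        elif s.startswith("nColumns="):
            try:
                n_cols = int(s.split("=", 1)[1])
            except ValueError:
                raise StoParseError("unreadable nColumns value", i + 1) from None
        elif s == "endheader":
            header_end = i
            break
    if header_end is None:
        raise StoParseError("missing 'endheader' sentinel")
    if header_end + 1 >= len(lines):
        raise StoParseError("no column header after endheader", header_end + 2)
    columns = lines[header_end + 1].split("\t")
    body = [l for l in lines[header_end + 2:] if l.strip()]
    data = []
    for j, line in enumerate(body):
        try:
            data.append([float(v) for v in line.split()])
        except ValueError:
            raise StoParseError("non-numeric body value",
                                header_end + 3 + j) from None
    df = pd.DataFrame(data, columns=columns)
    if n_cols is not None and df.shape[1] != n_cols:
        raise StoParseError(
            f"header declares nColumns={n_cols} but table has {df.shape[1]} columns")
    if n_rows is not None and df.shape[0] != n_rows:
        raise StoParseError(
            f"header declares nRows={n_rows} but table has {df.shape[0]} rows")
    return df


def read_kinematics(path) -> pd.DataFrame:
    """Read kinematics from .sto/.mot or plain delimited text (CSV/TSV).

    Returns a DataFrame with a ``time`` column first.
    """
    path = Path(path)
    if path.suffix.lower() in (".sto", ".mot"):
        df = read_sto(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0] != "time":
        raise ValueError("expected 'time' as the first column")
    return df
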