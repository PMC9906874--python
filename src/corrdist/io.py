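"""Reading and writing the delimited-text formats used across the package.

Expression matrices are plain delimited text (comma or tab, sniffed) with a
header row and a first column of identifiers.  Items (the things being
clustered -- genes or samples) live in rows internally; a file with items
in columns is transposed on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["read_expression_matrix", "write_expression_matrix"]


def read_expression_matrix(path, orientation: str = "items_in_rows") -> pd.DataFrame:
    """Read a labeled expression matrix from delimited text.

    Parameters
    ----------
    orientation
        ``"items_in_rows"`` (default) or ``"items_in_columns"``; the
        returned DataFrame always has items in rows.
    """
    if orientation not in ("items_in_rows", "items_in_columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= max(1, header.count(",")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "items_in_columns":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.empty:
        raise ValidationError(f"{path}: empty matrix")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate item identifier {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValidationError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise ValidationError(f"{path}: non-numeric values") from None
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{path}: non-finite value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return df.astype(float)


def write_expression_matrix(df: pd.DataFrame, path):
    """Write at full double precision so a round trip is bit-exact."""
    df.to_csv(path, float_format=lambda v: format(v, ".17g"))
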