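"""Matrix containers, normalisation and delimited-text I/O.

All matrices are pandas DataFrames with samples (cells) as rows and
genes as columns.  Expression values are log pseudocounts
``x = log(x_norm + 1)`` and are finite and non-negative.  Binary
activity matrices use float values ``{0.0, 1.0, NaN}`` where NaN marks
the UNDETERMINED state; on disk the undetermined token is configurable
("?" by default, "NA" dialect supported).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "UNDETERMINED",
    "is_undetermined",
    "validate_counts",
    "validate_expression",
    "validate_binary",
    "validate_boolean_states",
    "normalize_log1p",
    "read_expression",
    "write_expression",
    "read_binary",
    "write_binary",
    "read_boolean_states",
]

#: Internal symbol for the undetermined activity state.
UNDETERMINED = np.nan


def is_undetermined(values) -> np.ndarray:
    """Boolean mask of undetermined entries."""
    return pd.isna(values)


def _check_unique(index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


def validate_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw count matrix (cells x genes, non-negative integers)."""
    _check_unique(raw.index, "cell ids")
    _check_unique(raw.columns, "gene ids")
    values = raw.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("count matrix must be numeric")
    if np.any(values < 0):
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix contains non-integral entries")
    return raw


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a log-pseudocount matrix: finite, non-negative, unique ids."""
    _check_unique(matrix.index, "cell ids")
    _check_unique(matrix.columns, "gene ids")
    values = matrix.to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite entries")
    if np.any(values < 0):
        raise ValueError("expression matrix contains negative entries")
    return matrix


def validate_binary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a three-valued activity matrix ({0, 1, NaN})."""
    values = matrix.to_numpy(dtype=float)
    determined = values[~np.isnan(values)]
    if not np.isin(determined, (0.0, 1.0)).all():
        raise ValueError("binary matrix entries must be 0, 1 or undetermined")
    return matrix


def validate_boolean_states(states: pd.DataFrame) -> pd.DataFrame:
    """Validate a strictly binary Boolean state matrix (samples x nodes)."""
    values = states.to_numpy()
    if pd.isna(values).any():
        raise ValueError(
            "Boolean state matrix contains undetermined entries; resolve them "
            "upstream (e.g. with profiles-guided filling) before sampling"
        )
    if not np.isin(values.astype(float), (0.0, 1.0)).all():
        raise ValueError("Boolean state matrix entries must be exactly 0 or 1")
    return states


def normalize_log1p(raw: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Library-size normalise counts and take log1p.

    Each cell c is scaled by its size factor ``S_c = sum_g raw_cg / scale``
    (scale=1e6 gives counts per million), then ``x = log(raw/S_c + 1)``.
    Zero counts map to exactly 0; cells with zero total are rejected.
    """
    validate_counts(raw)
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = raw.sum(axis=1).to_numpy(dtype=float)
    if np.any(totals == 0):
        zero_cells = raw.index[totals == 0].tolist()
        raise ValueError(f"cells with all-zero counts (size factor 0): {zero_cells[:5]}")
    norm = raw.to_numpy(dtype=float) / (totals[:, None] / scale)
    out = pd.DataFrame(np.log1p(norm), index=raw.index, columns=raw.columns)
    return out


def read_expression(
    path,
    delimiter: str = ",",
    orientation: str = "cells_by_genes",
) -> pd.DataFrame:
    """Read a delimited expression matrix (header row + index column).

    orientation="genes_by_cells" transposes the parsed table so that the
    in-memory layout is always cells x genes.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in expression matrix: {exc}") from exc
    return validate_expression(df)


def write_expression(matrix: pd.DataFrame, path, delimiter: str = ",") -> None:
    matrix.to_csv(path, sep=delimiter)


def read_binary(
    path,
    delimiter: str = ",",
    undetermined_token: str = "?",
) -> pd.DataFrame:
    """Read a three-valued activity matrix written by :func:`write_binary`."""
    df = pd.read_csv(
        path, sep=delimiter, index_col=0, na_values=[undetermined_token],
        keep_default_na=(undetermined_token == "NA"), dtype=str,
    )
    out = df.apply(pd.to_numeric, errors="raise").astype(float)
    return validate_binary(out)


def write_binary(
    matrix: pd.DataFrame,
    path,
    delimiter: str = ",",
    undetermined_token: str = "?",
) -> None:
    """Write a three-valued matrix; undetermined entries become the token."""
    if undetermined_token in ("0", "1"):
        raise ValueError("undetermined token collides with 0/1 symbols")
    validate_binary(matrix)
    out = matrix.copy()
    # integers for determined entries, token for NaN
    text = out.map(lambda v: undetermined_token if pd.isna(v) else str(int(v)))
    text.to_csv(path, sep=delimiter)


def read_boolean_states(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a strictly binary Boolean state/trace matrix (samples x nodes)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return validate_boolean_states(df.astype(int))
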