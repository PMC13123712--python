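"""TSV readers and writers.

All files are tab-separated UTF-8 with ``NA`` for missing values.
Count tables have samples as rows (first column = sample id, header =
taxon ids); metadata and density tables are tidy, one record per row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import ParseError
from .tables import (
    RANKS,
    CellDensityTable,
    CountTable,
    validate_metadata,
)

_NA = "NA"


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return df.mask(df == _NA)


def read_count_table(
    path: str | os.PathLike, taxonomy_path: str | os.PathLike | None = None
) -> CountTable:
    """Read a samples-as-rows integer count table (and optional taxonomy)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 1 or raw.empty:
        raise ParseError(f"{path}: empty count table")
    raw = raw.set_index(raw.columns[0])
    mat = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            vals = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric count in column {col!r}") from exc
        if vals.isna().any():
            bad = raw.index[vals.isna()][0]
            raise ParseError(f"{path}: missing count at row {bad!r}, column {col!r}")
        if (vals != vals.round()).any():
            bad = raw.index[vals != vals.round()][0]
            raise ParseError(
                f"{path}: non-integer count at row {bad!r}, column {col!r}"
            )
        mat[col] = vals.astype(np.int64)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    return CountTable(mat, taxonomy=taxonomy)


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    """Read a taxon -> rank lineage table (first column = taxon id)."""
    raw = _read_tsv(path)
    if raw.empty:
        raise ParseError(f"{path}: empty taxonomy table")
    raw = raw.set_index(raw.columns[0])
    missing = [r for r in RANKS if r not in raw.columns]
    if missing:
        raise ParseError(f"{path}: taxonomy missing rank column(s): {missing}")
    return raw[list(RANKS)]


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate sample metadata; enum labels are case-insensitive."""
    raw = _read_tsv(path)
    if raw.empty:
        raise ParseError(f"{path}: empty metadata table")
    return validate_metadata(raw)


def read_density_table(path: str | os.PathLike) -> CellDensityTable:
    """Read a tidy immune-cell density table."""
    raw = _read_tsv(path)
    if raw.empty:
        raise ParseError(f"{path}: empty density table")
    raw["density"] = pd.to_numeric(raw["density"], errors="raise")
    return CellDensityTable(raw)


def write_table(result, path: str | os.PathLike) -> None:
    """Write any tabular result as TSV, round-trippable to 12 significant digits.

    Accepts a DataFrame or any of the domain wrappers with a ``.data``
    frame. NaN cells are written as ``NA``. Index is written when it is
    named or non-default (sample ids).
    """
    df = getattr(result, "data", result)
    if not isinstance(df, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    write_index = df.index.name is not None or not isinstance(
        df.index, pd.RangeIndex
    )
    if write_index and df.index.name is None:
        df = df.rename_axis("sample_id")
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.12g", index=write_index)
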