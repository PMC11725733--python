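"""Delimited-text schemas for the pipeline's tables.

Canonical interchange is plain CSV:

* ``metabolites.csv`` / ``quality.csv`` — ``sample_id`` index, then
  ``day``, ``replicate``, then one column per variable;
* ``spectra.csv`` — ``sample_id``, ``day``, ``replicate``,
  ``observation``, ``chem_id``, then one column per wavelength with the
  header cell holding the wavelength in nm (strictly increasing).

Loads are schema-validated; joins across tables are strict on
``sample_id`` and report unmatched ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SpectralDataset
from .errors import SchemaError

__all__ = [
    "write_table",
    "read_table",
    "write_spectra",
    "read_spectra",
    "check_join",
]

_META_COLS = ("day", "replicate")
_SPEC_META_COLS = ("day", "replicate", "observation", "chem_id")
_FLOAT_FMT = "%.10g"


def _check_index(df: pd.DataFrame, path) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicated sample_id {dup!r}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a metabolite or quality table (sample_id index)."""
    df.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_table(path: str | Path, kind: str = "table") -> pd.DataFrame:
    """Read and validate a metabolite or quality table."""
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    for col in _META_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    _check_index(df, path)
    value_cols = [c for c in df.columns if c not in _META_COLS]
    bad = [
        c for c in value_cols if not pd.api.types.is_numeric_dtype(df[c])
    ]
    if bad:
        raise SchemaError(f"{path}: non-numeric {kind} columns {bad[:5]}")
    return df


def write_spectra(ds: SpectralDataset, path: str | Path) -> None:
    """Write a spectral dataset as a wide CSV (wavelength-per-column)."""
    ds.to_frame().to_csv(
        path, index_label="sample_id", float_format=_FLOAT_FMT
    )


def read_spectra(path: str | Path) -> SpectralDataset:
    """Read a wide spectra CSV back into a :class:`SpectralDataset`."""
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    meta_cols = [c for c in _SPEC_META_COLS if c in df.columns]
    if "day" not in meta_cols:
        raise SchemaError(f"{path}: missing required column 'day'")
    _check_index(df, path)
    band_cols = [c for c in df.columns if c not in _SPEC_META_COLS]
    try:
        wl = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise SchemaError(
            f"{path}: wavelength headers must be numeric (nm): {exc}"
        ) from exc
    if np.any(np.diff(wl) <= 0):
        raise SchemaError(
            f"{path}: wavelength headers must be strictly increasing in nm"
        )
    return SpectralDataset(
        wl, df[band_cols].to_numpy(float), df[meta_cols]
    )


def check_join(left: pd.DataFrame, right: pd.DataFrame,
               left_name: str = "left", right_name: str = "right") -> None:
    """Require identical sample_id sets; report the mismatches."""
    only_l = left.index.difference(right.index)
    only_r = right.index.difference(left.index)
    if len(only_l) or len(only_r):
        raise SchemaError(
            f"sample_id mismatch: {len(only_l)} only in {left_name} "
            f"(e.g. {list(only_l[:3])}), {len(only_r)} only in "
            f"{right_name} (e.g. {list(only_r[:3])})"
        )
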