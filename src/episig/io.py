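"""Readers and writers for the pipeline's plain-text formats.

All matrices are TSV with the probe id in the first column and sample ids
in the header; the sample sheet is CSV indexed by sample id; the manifest
is a BED-like TSV (0-based half-open coordinates). Parsing is strict:
duplicate ids, ragged rows and out-of-range values are reported with the
offending row/column rather than silently coerced.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd


class ParseError(ValueError):
    pass


def _read_tsv_matrix(path, value_range: tuple[float, float] | None) -> pd.DataFrame:
    path = pathlib.Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate probe ids {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    if value_range is not None:
        lo, hi = value_range
        vals = df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < lo) | (vals > hi)  # NaN compares False: missing allowed
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"{path}: value {vals[i, j]!r} out of [{lo}, {hi}] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
    return df


def read_beta_matrix(path) -> pd.DataFrame:
    """Beta matrix TSV; every value must lie in [0, 1] or be missing (NA)."""
    return _read_tsv_matrix(path, (0.0, 1.0))


def read_detp_matrix(path) -> pd.DataFrame:
    """Detection p-value matrix TSV; values in [0, 1]."""
    return _read_tsv_matrix(path, (0.0, 1.0))


def write_matrix(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", float_format="%.17g", index_label=index_label,
                            na_rep="NA")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    required = {"chrom", "start", "end", "snp_flag", "crossreactive_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate probe ids in manifest")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ParseError(f"{path}: start >= end for probe {bad!r}")
    df["snp_flag"] = df["snp_flag"].astype(bool)
    df["crossreactive_flag"] = df["crossreactive_flag"].astype(bool)
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    required = {"group", "age", "sex", "array_type", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    present_age = df["age"].dropna()
    if (present_age < 0).any():
        raise ParseError(f"{path}: negative age values")
    return df
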