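"""Reading and writing methylation beta matrices and annotation tables.

A beta matrix is stored as a :class:`pandas.DataFrame` with CpG probes as
rows and samples as columns, all entries methylation fractions in [0, 1]
(``NaN`` marks missing).  Delimited-text layout follows the GEO
series-matrix convention: first column holds probe identifiers, the header
row holds sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "beta_from_intensities",
    "read_beta_matrix",
    "write_beta_matrix",
    "validate_beta_matrix",
    "intersect_probes",
    "read_sample_table",
    "write_sample_table",
    "read_probe_table",
    "write_probe_table",
]

ISLAND_LEVELS = ("island", "shore", "outside")
SEX_LEVELS = ("female", "male", "unknown")


@dataclass(frozen=True)
class Dialect:
    """Delimited-text conventions for matrices and tables.

    Parameters
    ----------
    sep : column delimiter (tab by default).
    na_token : token written/recognised for missing values.
    out_of_range : what to do with values outside [0, 1] on read:
        ``"error"`` raises, ``"mask"`` replaces them with missing.
    """

    sep: str = "\t"
    na_token: str = "NA"
    out_of_range: str = "error"


def beta_from_intensities(M, U, offset: float = 100.0):
    """Methylation fraction from methylated / unmethylated intensities.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + offset).  Negative
    intensities are clamped to zero; the positive offset keeps the
    denominator away from zero, so the result lies in [0, 1).
    Accepts scalars or arrays (broadcast).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    if offset <= 0:
        raise ValueError("offset must be positive")
    Mc = np.maximum(M, 0.0)
    Uc = np.maximum(U, 0.0)
    out = Mc / (Mc + Uc + offset)
    return float(out) if out.ndim == 0 else out


def validate_beta_matrix(beta: pd.DataFrame, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Check invariants of a beta matrix; apply the out-of-range policy."""
    if beta.index.has_duplicates:
        raise ValueError("duplicate probe identifiers")
    if beta.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    values = beta.to_numpy(dtype=float)
    bad = (values < 0) | (values > 1)
    bad &= ~np.isnan(values)
    if bad.any():
        if dialect.out_of_range == "error":
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {values[i, j]!r} outside [0, 1] at "
                f"probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
            )
        elif dialect.out_of_range == "mask":
            values = values.copy()
            values[bad] = np.nan
            beta = pd.DataFrame(values, index=beta.index, columns=beta.columns)
        else:
            raise ValueError(f"unknown out_of_range policy {dialect.out_of_range!r}")
    return beta


def read_beta_matrix(path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    """Read a probe x sample beta matrix from delimited text."""
    df = pd.read_csv(
        path,
        sep=dialect.sep,
        index_col=0,
        na_values=[dialect.na_token],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return validate_beta_matrix(df, dialect)


def write_beta_matrix(beta: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    validate_beta_matrix(beta)
    beta.to_csv(path, sep=dialect.sep, na_rep=dialect.na_token, index_label="probe_id")


def intersect_probes(matrices: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict beta matrices to their shared probes, in common order.

    Mirrors merging array platforms on the probes present on all of them.
    Probe order follows the first matrix.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    shared = set(matrices[0].index)
    for m in matrices[1:]:
        shared &= set(m.index)
    if not shared:
        raise ValueError("probe intersection is empty")
    order = [p for p in matrices[0].index if p in shared]
    return [m.loc[order] for m in matrices]


# -- sample / probe annotation tables ---------------------------------------

SAMPLE_COLUMNS = ["sample_id", "age", "sex", "disease", "tissue", "dataset"]
PROBE_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "chromosome",
    "island_status",
    "pcg_occupancy",
    "distance_to_tss",
    "polymorphic",
    "cross_reactive",
]


def read_sample_table(path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, na_values=[dialect.na_token], keep_default_na=False)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["age"] = df["age"].astype(float)
    if (df["age"].dropna() < 0).any():
        raise ValueError("negative age in sample table")
    bad_sex = set(df["sex"].dropna()) - set(SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
    return df


def write_sample_table(samples: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    samples.to_csv(path, sep=dialect.sep, na_rep=dialect.na_token, index=False)


def read_probe_table(path, dialect: Dialect = Dialect()) -> pd.DataFrame:
    df = pd.read_csv(path, sep=dialect.sep, na_values=[dialect.na_token], keep_default_na=False)
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    df["probe_id"] = df["probe_id"].astype(str)
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in probe table")
    bad = set(df["island_status"].dropna()) - set(ISLAND_LEVELS)
    if bad:
        raise ValueError(f"unknown island_status levels: {sorted(bad)}")
    df["pcg_occupancy"] = df["pcg_occupancy"].astype(int)
    if not df["pcg_occupancy"].isin([0, 1, 2, 3]).all():
        raise ValueError("pcg_occupancy must be in 0..3")
    for col in ("polymorphic", "cross_reactive"):
        df[col] = df[col].astype(bool)
    return df


def write_probe_table(probes: pd.DataFrame, path, dialect: Dialect = Dialect()) -> None:
    probes.to_csv(path, sep=dialect.sep, na_rep=dialect.na_token, index=False)


def align_samples(beta: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Return the sample table rows matching the beta matrix columns, in order."""
    table = samples.set_index("sample_id")
    missing = [s for s in beta.columns if s not in table.index]
    if missing:
        raise ValueError(f"samples absent from sample table: {missing[:5]}")
    return table.loc[list(beta.columns)].reset_index()
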