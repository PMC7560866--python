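"""Tabular containers for omics data matrices and covariate tables.

The package works on a plain samples-by-variables numeric matrix with string
identifiers on both axes. Missing values are represented as NaN throughout;
downstream correlation estimators require a complete matrix, which the
preprocessing chain (:mod:`priorcut.preprocess`) guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Cell contents treated as missing when reading TSV matrices.
MISSING_TOKENS = ("", "NA", "NaN", "nan")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """Samples x variables abundance matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_variables)
        Numeric abundances; NaN marks a missing measurement.
    sample_ids : list of str
        Unique row identifiers.
    variable_ids : list of str
        Unique column identifiers.
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.variable_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variable_ids)} variables"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.variable_ids, "variable")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), list(self.sample_ids), list(self.variable_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OmicsMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class CovariateTable:
    """Samples x covariates table; columns may be numeric or categorical."""

    values: pd.DataFrame
    sample_ids: list[str] = field(init=False)
    covariate_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.values.index]
        self.covariate_names = [str(c) for c in self.values.columns]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.covariate_names, "covariate")

    def design_matrix(self) -> pd.DataFrame:
        """Intercept + covariates, categoricals one-hot encoded dropping the
        first level. Constant columns duplicate the intercept and are
        dropped (an all-constant covariate table degrades to intercept-only)."""
        parts = [pd.Series(1.0, index=self.values.index, name="intercept")]
        for name in self.covariate_names:
            col = self.values[name]
            if pd.api.types.is_numeric_dtype(col):
                if col.nunique(dropna=False) > 1:
                    parts.append(col.astype(float))
            else:
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                parts.append(dummies)
        return pd.concat(parts, axis=1)


def _read_string_table(path, missing_tokens) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for name in header:  # pandas silently mangles duplicate header names
        if name in seen:
            raise ValueError(f"duplicate column name: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row ID: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column name: {dup!r}")
    return df.replace(list(missing_tokens), np.nan)


def _to_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return out


def read_data_matrix(
    path,
    orientation: str = "samples_in_rows",
    missing_tokens=MISSING_TOKENS,
) -> OmicsMatrix:
    """Read a TSV data matrix (header row + leading ID column).

    ``orientation='variables_in_rows'`` transposes the parsed table so that the
    returned matrix is always samples x variables.
    """
    if orientation not in ("samples_in_rows", "variables_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_string_table(path, missing_tokens))
    if orientation == "variables_in_rows":
        df = df.T
    return OmicsMatrix.from_frame(df)


def write_data_matrix(x: OmicsMatrix, path) -> None:
    x.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_covariates(path, missing_tokens=MISSING_TOKENS) -> CovariateTable:
    """Read a covariate TSV; columns that parse fully as numbers become numeric."""
    df = _read_string_table(path, missing_tokens)
    out = {}
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        fully_numeric = not (numeric.isna() & df[col].notna()).any()
        out[col] = numeric if fully_numeric else df[col]
    return CovariateTable(pd.DataFrame(out, index=df.index))


def write_covariates(c: CovariateTable, path) -> None:
    c.values.to_csv(path, sep="\t", na_rep="NA")
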