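"""Replicate metabolite profiles and the covariance estimate driving the inverse problem.

The covariance of biological replicates around steady state is the data-side
input of the Lyapunov inversion.  By default it is computed on mean-centered
raw intensities with the unbiased (n-1) estimator; Pareto scaling belongs to
the multivariate discriminant workflow, not here, but both transforms are
exposed so the preprocessing can be configured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "CovarianceMatrix",
    "read_profiles",
    "sample_covariance",
    "pareto_scale",
    "log_transform",
]


@dataclass
class ProfileMatrix:
    """Replicates x metabolites intensity table with a condition label per sample."""

    values: np.ndarray
    metabolite_ids: list[str]
    sample_ids: list[str]
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x metabolites)")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.condition) != n:
            raise ValueError("sample_ids/condition length must match number of rows")
        if len(self.metabolite_ids) != p:
            raise ValueError("metabolite_ids length must match number of columns")
        if len(set(self.metabolite_ids)) != p:
            raise ValueError("duplicate metabolite ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        out: list[str] = []
        for c in self.condition:
            if c not in out:
                out.append(c)
        return out

    def by_condition(self, label: str) -> "ProfileMatrix":
        """Sub-matrix of samples carrying the given condition label."""
        idx = [i for i, c in enumerate(self.condition) if c == label]
        if not idx:
            raise KeyError(f"condition {label!r} not present (have {self.conditions})")
        return ProfileMatrix(
            values=self.values[idx],
            metabolite_ids=list(self.metabolite_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            condition=[label] * len(idx),
        )

    def to_dataframe(self, condition_column: str = "condition") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.metabolite_ids)
        df.insert(0, condition_column, self.condition)
        return df

    def write(self, path: str | Path, condition_column: str = "condition") -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.to_dataframe(condition_column).to_csv(path, sep=sep, index_label="sample")


@dataclass
class CovarianceMatrix:
    """Symmetric metabolite x metabolite covariance with its sample count."""

    values: np.ndarray
    n_samples: int
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.metabolite_ids)
        if self.values.shape != (p, p):
            raise ValueError("covariance shape inconsistent with metabolite_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8 * (1 + np.abs(self.values).max())):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(self.values) < -1e-12):
            raise ValueError("covariance diagonal has negative entries")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.metabolite_ids, columns=self.metabolite_ids)

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def read_profiles(
    path: str | Path,
    condition_column: str = "condition",
    sample_column: str | None = None,
) -> ProfileMatrix:
    """Read a wide CSV/TSV profile table (rows = samples, columns = metabolites).

    The table must contain ``condition_column``; every other non-index column
    is treated as a metabolite and must be fully numeric.  Missing values are
    rejected (the targeted panels this models are complete by design).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0 if sample_column is None else None)
    if sample_column is not None:
        if sample_column not in df.columns:
            raise ValueError(f"sample column {sample_column!r} not found in {path}")
        df = df.set_index(sample_column)
    if condition_column not in df.columns:
        raise ValueError(
            f"condition column {condition_column!r} not found in {path} "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    condition = df[condition_column].astype(str).tolist()
    data = df.drop(columns=[condition_column])
    for col in data.columns:
        numeric = pd.to_numeric(data[col], errors="coerce")
        bad = numeric.isna() & data[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(f"non-numeric value {data.loc[row, col]!r} at row {row!r}, column {col!r}")
        if numeric.isna().any():
            row = numeric.isna().idxmax()
            raise ValueError(f"missing value at row {row!r}, column {col!r}; imputation is not supported")
        data[col] = numeric
    return ProfileMatrix(
        values=data.to_numpy(dtype=float),
        metabolite_ids=[str(c) for c in data.columns],
        sample_ids=[str(i) for i in data.index],
        condition=condition,
    )


def sample_covariance(p: ProfileMatrix) -> CovarianceMatrix:
    """Unbiased (n-1 denominator) covariance of metabolites over replicates."""
    if p.n_samples < 2:
        raise ValueError(f"covariance requires >=2 samples, got {p.n_samples}")
    cov = np.cov(p.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0  # symmetrize away round-off
    return CovarianceMatrix(values=cov, n_samples=p.n_samples, metabolite_ids=list(p.metabolite_ids))


def pareto_scale(p: ProfileMatrix, allow_constant: bool = False) -> ProfileMatrix:
    """Mean-center each metabolite and divide by the square root of its SD.

    Pareto scaling shrinks the dominance of high-abundance metabolites while
    keeping more of the original variance structure than unit-variance
    scaling; a column with SD s ends up with SD sqrt(s).
    """
    x = p.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        names = [p.metabolite_ids[i] for i in np.nonzero(zero)[0]]
        if not allow_constant:
            raise ValueError(
                f"constant metabolite column(s) {names}: Pareto scaling undefined "
                "(pass allow_constant=True to zero them)"
            )
        warnings.warn(f"constant metabolite column(s) {names} set to zero under Pareto scaling")
    denom = np.where(zero, 1.0, np.sqrt(sd))
    scaled = (x - mean) / denom
    scaled[:, zero] = 0.0
    return ProfileMatrix(scaled, list(p.metabolite_ids), list(p.sample_ids), list(p.condition))


def log_transform(p: ProfileMatrix, base: float = np.e, pseudocount: float = 0.0) -> ProfileMatrix:
    """Elementwise log of intensities (optional preprocessing before covariance)."""
    if base <= 1:
        raise ValueError("log base must be > 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = p.values + pseudocount
    if np.any(shifted <= 0):
        i, j = np.unravel_index(np.argmin(shifted), shifted.shape)
        raise ValueError(
            f"non-positive value {p.values[i, j]} + pseudocount at sample "
            f"{p.sample_ids[i]!r}, metabolite {p.metabolite_ids[j]!r}"
        )
    vals = np.log(shifted) / np.log(base)
    return ProfileMatrix(vals, list(p.metabolite_ids), list(p.sample_ids), list(p.condition))
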