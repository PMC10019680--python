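"""Differential Jacobian: compare two conditions' ensembles and rank perturbed entries.

For each structurally allowed Jacobian entry the score is the absolute
difference of the two conditions' ensemble medians normalized by the square
of the pooled interquartile range:

    score(i,j) = |median_b - median_a| / max(pooled_iqr^2, epsilon),
    pooled_iqr = (iqr_a + iqr_b) / 2 .

Large scores flag reaction elasticities whose reconstructed value moved far
relative to the Monte-Carlo uncertainty of the two reconstructions — the
readout that localizes a metabolic perturbation to specific couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import JacobianEnsemble

__all__ = ["DifferentialJacobian", "differential_jacobian", "rank_perturbations"]


@dataclass
class DifferentialJacobian:
    """Per-entry perturbation scores between two conditions, with ranking."""

    delta: np.ndarray  # non-negative scores, exact 0 off mask
    signed_difference: np.ndarray  # median_b - median_a (for interpretation)
    mask: np.ndarray
    metabolite_ids: list[str]
    labels: tuple[str, str]
    epsilon: float
    median_a: np.ndarray
    median_b: np.ndarray
    iqr_a: np.ndarray
    iqr_b: np.ndarray

    @property
    def ranking(self) -> list[tuple[str, str, float]]:
        """(row metabolite, column metabolite, score), descending; ties by (row, col) index."""
        rows, cols = np.nonzero(self.mask)
        order = sorted(
            range(rows.size), key=lambda k: (-self.delta[rows[k], cols[k]], rows[k], cols[k])
        )
        ids = self.metabolite_ids
        return [
            (ids[rows[k]], ids[cols[k]], float(self.delta[rows[k], cols[k]])) for k in order
        ]


def differential_jacobian(
    a: JacobianEnsemble,
    b: JacobianEnsemble,
    epsilon: float | None = None,
    normalization: str = "pooled",
) -> DifferentialJacobian:
    """Score every masked entry by |median difference| / pooled-IQR squared.

    ``epsilon`` floors the squared-IQR denominator; by default it is 1e-6
    times the largest pooled IQR over masked entries (with an absolute floor
    so zero-spread ensembles stay finite).  ``normalization='per_condition'``
    instead normalizes each condition's median by its own squared IQR before
    differencing.
    """
    if a.metabolite_ids != b.metabolite_ids:
        raise ValueError("ensembles have different metabolite order")
    if not np.array_equal(a.mask, b.mask):
        raise ValueError("ensembles have different sparsity masks")
    mask = a.mask
    pooled = (a.iqr + b.iqr) / 2.0
    if epsilon is None:
        top = float(pooled[mask].max()) if mask.any() else 0.0
        epsilon = max(1e-6 * top, 1e-12)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    denom = np.maximum(pooled**2, epsilon)
    if normalization == "pooled":
        signed = b.median - a.median
        delta = np.abs(signed) / denom
    elif normalization == "per_condition":
        da = np.maximum(a.iqr**2, epsilon)
        db = np.maximum(b.iqr**2, epsilon)
        signed = b.median / db - a.median / da
        delta = np.abs(signed)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    delta = np.where(mask, delta, 0.0)
    signed = np.where(mask, signed, 0.0)
    return DifferentialJacobian(
        delta=delta,
        signed_difference=signed,
        mask=mask,
        metabolite_ids=list(a.metabolite_ids),
        labels=(a.condition_label, b.condition_label),
        epsilon=epsilon,
        median_a=a.median,
        median_b=b.median,
        iqr_a=a.iqr,
        iqr_b=b.iqr,
    )


def entry_label(row: str, col: str) -> str:
    """Human-readable label for Jacobian entry (row, col): sensitivity of the
    row metabolite's net rate to the column metabolite's concentration."""
    return f"∂f_{row}/∂f_{col}"


def rank_perturbations(d: DifferentialJacobian, top_k: int | None = None) -> pd.DataFrame:
    """Top-k report of the most perturbed Jacobian entries.

    Columns: rank, row/column metabolite, entry label, score, signed median
    difference and the per-condition medians and IQRs behind it.
    Deterministic tie-break by (row index, column index).
    """
    ranking = d.ranking
    if top_k is None:
        top_k = len(ranking)
    if top_k > len(ranking):
        import warnings

        warnings.warn(
            f"top_k={top_k} exceeds {len(ranking)} masked entries; truncating"
        )
        top_k = len(ranking)
    idx = {m: i for i, m in enumerate(d.metabolite_ids)}
    rows = []
    for rank, (r, c, score) in enumerate(ranking[:top_k], start=1):
        i, j = idx[r], idx[c]
        rows.append(
            {
                "rank": rank,
                "row_metabolite": r,
                "col_metabolite": c,
                "entry": entry_label(r, c),
                "score": score,
                "signed_difference": d.signed_difference[i, j],
                f"median_{d.labels[0] or 'a'}": d.median_a[i, j],
                f"median_{d.labels[1] or 'b'}": d.median_b[i, j],
                f"iqr_{d.labels[0] or 'a'}": d.iqr_a[i, j],
                f"iqr_{d.labels[1] or 'b'}": d.iqr_b[i, j],
            }
        )
    return pd.DataFrame(rows)


def write_report(d: DifferentialJacobian, path: str | Path, top_k: int | None = None) -> None:
    rank_perturbations(d, top_k).to_csv(path, sep="\t", index=False)
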