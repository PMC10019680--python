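"""Jacobian reconstruction from covariance via the stochastic Lyapunov equation.

Around a stable metabolic steady state, concentration fluctuations behave as
an Ornstein-Uhlenbeck process whose stationary covariance C is tied to the
Jacobian J and the fluctuation (diffusion) matrix F by the Lyapunov equation

.. math:: J C + C J^T = -2 F .

The forward direction (J, F -> C) is a standard linear matrix equation.  The
inverse direction (C, F -> J) is the reconstruction step: it is made
identifiable by parameterizing J through the network,
:math:`J = N \\cdot E` with N the stoichiometric matrix and E the elasticity
matrix restricted to the structural sparsity pattern.  The upper triangle of
the symmetric Lyapunov residual supplies n(n+1)/2 independent scalar
equations, linear in the free elasticities, solved by (optionally ridge
regularized) least squares.

Because the true fluctuation magnitudes are unknown for real data, the
inversion is repeated over a Monte-Carlo ensemble of sampled fluctuation
matrices; per-entry medians and interquartile ranges over the ensemble are
the reported reconstruction and its uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.linalg

from .network import MetabolicNetwork, jacobian_sparsity
from .profiles import CovarianceMatrix

__all__ = [
    "FluctuationModel",
    "InverseProblem",
    "JacobianEnsemble",
    "StabilityReport",
    "solve_lyapunov_forward",
    "sample_fluctuation",
    "invert_once",
    "ensemble_invert",
    "stability_report",
]


# ---------------------------------------------------------------------------
# fluctuation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluctuationModel:
    """Log-normal sampler for diagonal fluctuation matrices.

    Draw ``d`` produces ``diag(base_intensity * exp(spread * z))`` with z
    i.i.d. standard normal from a substream addressed by ``(seed, d)``, so
    draws are reproducible independently of evaluation order.  The entrywise
    median over draws equals ``base_intensity`` and every draw is positive
    definite.  ``spread=0`` gives exactly ``diag(base_intensity)``.
    """

    base_intensity: np.ndarray
    spread: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        base = np.atleast_1d(np.asarray(self.base_intensity, dtype=float))
        object.__setattr__(self, "base_intensity", base)
        if np.any(base <= 0):
            raise ValueError("base_intensity must be strictly positive")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    @classmethod
    def from_covariance(
        cls, cov: CovarianceMatrix | np.ndarray, rel: float = 0.1, spread: float = 0.2, seed: int = 0
    ) -> "FluctuationModel":
        """Default calibration: base = rel * diag(COV) (fluctuation scaled to observed variance)."""
        values = cov.values if isinstance(cov, CovarianceMatrix) else np.asarray(cov)
        diag = np.diag(values).copy()
        if np.any(diag <= 0):
            raise ValueError("covariance diagonal must be positive to calibrate fluctuations")
        return cls(base_intensity=rel * diag, spread=spread, seed=seed)


def sample_fluctuation(model: FluctuationModel, n_metabolites: int, draw_index: int) -> np.ndarray:
    """Diagonal PSD fluctuation matrix for one Monte-Carlo draw."""
    base = model.base_intensity
    if base.size == 1:
        base = np.full(n_metabolites, base[0])
    if base.size != n_metabolites:
        raise ValueError(f"base_intensity has {base.size} entries, expected {n_metabolites}")
    if model.spread == 0:
        return np.diag(base)
    rng = np.random.default_rng(np.random.SeedSequence(model.seed, spawn_key=(draw_index,)))
    z = rng.standard_normal(n_metabolites)
    return np.diag(base * np.exp(model.spread * z))


# ---------------------------------------------------------------------------
# forward solver
# ---------------------------------------------------------------------------


def stability_report(j: np.ndarray) -> "StabilityReport":
    """Eigenvalues and Hurwitz flag (all real parts < 0) of a Jacobian."""
    j = np.asarray(j, dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise ValueError("Jacobian must be square")
    eig = np.linalg.eigvals(j)
    return StabilityReport(eigenvalues=eig, stable=bool(np.all(eig.real < 0)))


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray
    stable: bool

    @property
    def spectral_abscissa(self) -> float:
        return float(self.eigenvalues.real.max())


def solve_lyapunov_forward(jac: np.ndarray, flu: np.ndarray) -> np.ndarray:
    """Stationary covariance C solving J C + C J^T = -2 F.

    Requires a Hurwitz-stable J and symmetric PSD F; the returned C is
    symmetrized and its residual checked against the equation.
    """
    jac = np.asarray(jac, dtype=float)
    flu = np.asarray(flu, dtype=float)
    if jac.shape != flu.shape or jac.ndim != 2 or jac.shape[0] != jac.shape[1]:
        raise ValueError("jac and flu must be square matrices of equal shape")
    if not np.allclose(flu, flu.T, atol=1e-10 * (1 + np.abs(flu).max())):
        raise ValueError("fluctuation matrix must be symmetric")
    if not stability_report(jac).stable:
        raise ValueError("non-stable Jacobian: Lyapunov equation has no stationary solution")
    c = scipy.linalg.solve_continuous_lyapunov(jac, -2.0 * flu)
    c = (c + c.T) / 2.0
    resid = np.linalg.norm(jac @ c + c @ jac.T + 2.0 * flu)
    if resid > 1e-10 * (1.0 + np.linalg.norm(c)):
        raise ArithmeticError(f"Lyapunov solve residual too large: {resid:.3e}")
    return c


# ---------------------------------------------------------------------------
# single inversion
# ---------------------------------------------------------------------------

Mode = Literal["elasticity", "direct"]


def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def _design_elasticity(net: MetabolicNetwork, c: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Design matrix mapping free elasticities to upper-triangle Lyapunov entries.

    For J = N E, equation (i, j) of J C + C J^T reads
    sum_k e_k * (N[i,pk] C[qk,j] + N[j,pk] C[qk,i]), e_k the elasticity at
    (reaction pk, metabolite qk).
    """
    s = net.stoichiometry.astype(float)
    free = net.free_elasticity_index()
    iu, ju = _upper_indices(net.n_metabolites)
    a = np.empty((iu.size, len(free)))
    for k, (p, q) in enumerate(free):
        a[:, k] = s[iu, p] * c[q, ju] + s[ju, p] * c[q, iu]
    return a, free


def _design_direct(mask: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Design matrix for unknowns = Jacobian entries on the structural mask."""
    n = mask.shape[0]
    free = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]
    iu, ju = _upper_indices(n)
    a = np.zeros((iu.size, len(free)))
    for k, (r, cc) in enumerate(free):
        a[:, k] = (iu == r) * c[cc, ju] + (ju == r) * c[cc, iu]
    return a, free


def _solve_ls(a: np.ndarray, b: np.ndarray, ridge: float) -> tuple[np.ndarray, int]:
    if ridge > 0:
        aug = np.vstack([a, np.sqrt(ridge) * np.eye(a.shape[1])])
        rhs = np.concatenate([b, np.zeros(a.shape[1])])
        x, _, rank, _ = np.linalg.lstsq(aug, rhs, rcond=None)
        return x, a.shape[1]
    x, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    return x, int(rank)


def system_rank(
    cov: CovarianceMatrix | np.ndarray, net: MetabolicNetwork, mode: Mode = "elasticity"
) -> tuple[int, int]:
    """Numerical rank of the inverse-problem design matrix vs. its unknown count.

    The problem is determinate (unique least-squares solution) iff the rank
    equals the number of free parameters.  Rank deficiency at a given
    covariance signals genuine unidentifiability: some sparsity-respecting
    perturbation D satisfies D C + C D^T = 0.
    """
    c = cov.values if isinstance(cov, CovarianceMatrix) else np.asarray(cov, dtype=float)
    if mode == "elasticity":
        a, free = _design_elasticity(net, c)
    else:
        a, free = _design_direct(jacobian_sparsity(net), c)
    return int(np.linalg.matrix_rank(a)), len(free)


def invert_once(
    cov: CovarianceMatrix | np.ndarray,
    flu: np.ndarray,
    net: MetabolicNetwork,
    ridge: float = 1e-8,
    mode: Mode = "elasticity",
    return_elasticities: bool = False,
):
    """One Lyapunov inversion: recover J (and optionally E) from COV and one FLU.

    ``mode='elasticity'`` (default) solves for the free entries of E under
    J = N E; ``mode='direct'`` solves for Jacobian entries on the structural
    sparsity mask.  With ``ridge=0`` a rank-deficient system yields the
    minimum-norm solution plus an "under-determined" warning.
    """
    c = cov.values if isinstance(cov, CovarianceMatrix) else np.asarray(cov, dtype=float)
    flu = np.asarray(flu, dtype=float)
    n = net.n_metabolites
    if c.shape != (n, n) or flu.shape != (n, n):
        raise ValueError(
            f"dimension mismatch: network has {n} metabolites, cov {c.shape}, flu {flu.shape}"
        )
    if isinstance(cov, CovarianceMatrix) and cov.metabolite_ids != net.metabolite_ids:
        raise ValueError("covariance metabolite order differs from network order")

    iu, ju = _upper_indices(n)
    b = -2.0 * flu[iu, ju]
    if mode == "elasticity":
        a, free = _design_elasticity(net, c)
    elif mode == "direct":
        a, free = _design_direct(jacobian_sparsity(net), c)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if a.shape[1] == 0:
        raise ValueError("network has no free parameters (empty elasticity pattern)")

    x, rank = _solve_ls(a, b, ridge)
    if ridge == 0 and rank < a.shape[1]:
        warnings.warn(
            f"under-determined inversion: rank {rank} < {a.shape[1]} unknowns; "
            "returning minimum-norm solution"
        )

    if mode == "elasticity":
        e = np.zeros((net.n_reactions, n))
        for k, (p, q) in enumerate(free):
            e[p, q] = x[k]
        jac = net.stoichiometry.astype(float) @ e
    else:
        jac = np.zeros((n, n))
        for k, (r, cc) in enumerate(free):
            jac[r, cc] = x[k]
        e = None
    if return_elasticities:
        return jac, x, free
    return jac


# ---------------------------------------------------------------------------
# Monte-Carlo ensemble
# ---------------------------------------------------------------------------


@dataclass
class InverseProblem:
    """Bundle of everything one reconstruction needs."""

    cov: CovarianceMatrix
    network: MetabolicNetwork
    fluctuation: FluctuationModel
    n_draws: int = 1000
    ridge: float = 1e-8
    mode: Mode = "elasticity"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.cov.metabolite_ids != self.network.metabolite_ids:
            raise ValueError("covariance metabolite order differs from network order")


@dataclass
class JacobianEnsemble:
    """Stack of Monte-Carlo Jacobian solutions with per-entry median and IQR."""

    draws: np.ndarray  # (n_ok, n, n)
    median: np.ndarray
    iqr: np.ndarray
    mask: np.ndarray
    metabolite_ids: list[str]
    condition_label: str = ""
    elasticity_draws: np.ndarray | None = None  # (n_ok, n_free)
    free_index: list[tuple[int, int]] | None = None
    n_failed: int = 0

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def median_elasticities(self) -> np.ndarray:
        if self.elasticity_draws is None:
            raise ValueError("ensemble was not run in elasticity mode")
        return np.median(self.elasticity_draws, axis=0)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ids = self.metabolite_ids
        return (
            pd.DataFrame(self.median, index=ids, columns=ids),
            pd.DataFrame(self.iqr, index=ids, columns=ids),
        )

    def write(self, median_path: str | Path, iqr_path: str | Path) -> None:
        med, iqr = self.to_frames()
        med.to_csv(median_path, sep="\t")
        iqr.to_csv(iqr_path, sep="\t")


def ensemble_invert(
    problem: InverseProblem,
    condition_label: str = "",
    profiles: np.ndarray | None = None,
    bootstrap_cov: bool = False,
) -> JacobianEnsemble:
    """Monte-Carlo inversion: one :func:`invert_once` per sampled fluctuation matrix.

    Optionally also bootstrap-resamples the replicate rows used for the
    covariance each draw (``bootstrap_cov=True`` with ``profiles`` given).
    Draws whose linear system fails are skipped; at least 90% of draws must
    succeed.  Fully reproducible given the fluctuation model's seed.
    """
    net = problem.network
    n = net.n_metabolites
    if bootstrap_cov and profiles is None:
        raise ValueError("bootstrap_cov=True requires the replicate profile rows")
    mask = jacobian_sparsity(net)
    draws: list[np.ndarray] = []
    elas: list[np.ndarray] = []
    free_index: list[tuple[int, int]] | None = None
    n_failed = 0
    boot_rng = (
        np.random.default_rng(np.random.SeedSequence(problem.fluctuation.seed, spawn_key=(2**30,)))
        if bootstrap_cov
        else None
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-draw under-determination warnings would flood
        for d in range(problem.n_draws):
            flu = sample_fluctuation(problem.fluctuation, n, d)
            cov: CovarianceMatrix | np.ndarray = problem.cov
            if bootstrap_cov:
                assert profiles is not None and boot_rng is not None
                idx = boot_rng.integers(0, profiles.shape[0], size=profiles.shape[0])
                resampled = profiles[idx]
                c = np.cov(resampled, rowvar=False, ddof=1)
                cov = (c + c.T) / 2.0
            try:
                jac, x, free = invert_once(
                    cov, flu, net, ridge=problem.ridge, mode=problem.mode, return_elasticities=True
                )
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            draws.append(jac)
            elas.append(x)
            free_index = free
    if not draws:
        raise RuntimeError("all Monte-Carlo draws failed")
    if len(draws) < 0.9 * problem.n_draws:
        raise RuntimeError(
            f"only {len(draws)}/{problem.n_draws} draws succeeded (<90%); "
            "check covariance conditioning or increase ridge"
        )
    stack = np.stack(draws)
    q25, med, q75 = np.percentile(stack, [25, 50, 75], axis=0)
    elas_stack = np.stack(elas) if problem.mode == "elasticity" else None
    return JacobianEnsemble(
        draws=stack,
        median=med,
        iqr=q75 - q25,
        mask=mask,
        metabolite_ids=list(net.metabolite_ids),
        condition_label=condition_label,
        elasticity_draws=elas_stack,
        free_index=free_index,
        n_failed=n_failed,
    )
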