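"""Ground-truth synthetic data: stable metabolic Jacobians driving an
Ornstein-Uhlenbeck fluctuation process around steady state.

This module generates everything the reconstruction pipeline consumes, with
the truth known: a network, a ground-truth elasticity matrix E (hence
Jacobian J = N E), a diagonal fluctuation matrix F, the analytic stationary
covariance solving J C + C J^T = -2 F, and replicate "metabolite profiles"
simulated from the linear Langevin model

    dx = J x dt + sqrt(2 F) dW,

sampled after burn-in at decorrelating intervals, offset so intensities stay
positive.  A built-in D-serine synthesis network (PHGDH -> PSAT1 -> PSPH ->
SRR with NAD/NADH and Glu/KGA cofactor coupling through respiration-like
turnover reactions) provides the biologically structured test case; a padded
40-metabolite panel emulates a targeted-metabolomics screen where most
measured metabolites are bystanders.

Knockout-like conditions are produced by scaling a single reaction
elasticity (e.g. weakening the NADH-alpha-ketoglutarate coupling) and
recomputing the implied Jacobian and covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .inference import solve_lyapunov_forward, stability_report
from .network import MetabolicNetwork, Metabolite, Reaction, parse_network
from .profiles import ProfileMatrix

__all__ = [
    "KineticGroundTruth",
    "SimulationConfig",
    "build_serine_network",
    "build_panel_network",
    "random_network",
    "make_ground_truth",
    "perturb_condition",
    "simulate_ou",
    "generate_two_condition_dataset",
]


# Serine de novo synthesis from 3-phosphoglycerate, with the NAD/NADH couple
# closed by a respiration-like oxidation (NADHOX), alpha-ketoglutarate feeding
# NADH production (KGDH, the TCA-side coupling), and turnover/export sinks
# breaking the conservation relations so the Jacobian can be Hurwitz.
_SERINE_NETWORK_TEXT = """
# D-serine synthesis pathway with cofactor coupling
cofactors: NAD, NADH, Glu, KGA
PHGDH  : 3PG + NAD -> 3PHP + NADH
PSAT1  : 3PHP + Glu -> PSer + KGA
PSPH   : PSer -> LSer
SRR    : LSer -> DSer
NADHOX : NADH -> NAD
NADT   : NAD ->
KGDH   : KGA + NAD -> NADH
GLUT   : Glu ->
DSDEG  : DSer ->
"""


def build_serine_network() -> MetabolicNetwork:
    """The 9-metabolite D-serine synthesis network used throughout the tests.

    Metabolites: 3PG, NAD, 3PHP, NADH, Glu, PSer, KGA, LSer, DSer (in file
    order).  KGA is alpha-ketoglutarate (also written KEG); the KGDH reaction
    gives the Jacobian its NADH-row dependence on KGA.
    """
    return parse_network(_SERINE_NETWORK_TEXT)


def build_panel_network(n_total: int = 40, prefix: str = "MET") -> MetabolicNetwork:
    """Serine network padded with independent bystander metabolites, each with
    its own first-order turnover, to the size of a targeted screen."""
    net = build_serine_network()
    n_extra = n_total - net.n_metabolites
    if n_extra < 0:
        raise ValueError(f"panel size {n_total} smaller than core network ({net.n_metabolites})")
    mets = list(net.metabolites)
    rxns = list(net.reactions)
    for i in range(n_extra):
        mid = f"{prefix}{i + 1:02d}"
        mets.append(Metabolite(id=mid))
        rxns.append(Reaction(id=f"{mid}_turnover", substrates=((mid, 1),)))
    return MetabolicNetwork(mets, rxns)


def random_network(
    n_metabolites: int, n_conversions: int | None = None, seed: int = 0
) -> MetabolicNetwork:
    """Random determinate network: every metabolite gets a first-order
    degradation reaction plus random A -> B conversions (no self-loops,
    no duplicate edges)."""
    rng = np.random.default_rng(seed)
    if n_conversions is None:
        # keep free parameters (n + conversions) within the n(n+1)/2 equations
        n_conversions = min(n_metabolites, n_metabolites * (n_metabolites - 1) // 2)
    ids = [f"M{i + 1}" for i in range(n_metabolites)]
    mets = [Metabolite(id=m) for m in ids]
    rxns = [Reaction(id=f"deg_{m}", substrates=((m, 1),)) for m in ids]
    edges: set[tuple[int, int]] = set()
    attempts = 0
    while len(edges) < n_conversions and attempts < 50 * n_conversions:
        attempts += 1
        i, j = rng.integers(0, n_metabolites, size=2)
        if i == j or (int(i), int(j)) in edges:
            continue
        edges.add((int(i), int(j)))
    for k, (i, j) in enumerate(sorted(edges)):
        rxns.append(Reaction(id=f"conv{k + 1}", substrates=((ids[i], 1),), products=((ids[j], 1),)))
    return MetabolicNetwork(mets, rxns)


@dataclass
class KineticGroundTruth:
    """A known system: network, true elasticities/Jacobian/fluctuations and
    the analytic stationary covariance they imply."""

    network: MetabolicNetwork
    elasticities: np.ndarray  # reactions x metabolites, nonzero only on pattern
    jacobian: np.ndarray
    fluctuation: np.ndarray  # diagonal PSD
    covariance: np.ndarray  # analytic stationary covariance

    def free_elasticities(self) -> np.ndarray:
        """True values at the network's free elasticity positions (vectorized)."""
        return np.array([self.elasticities[p, q] for p, q in self.network.free_elasticity_index()])

    @property
    def stationary_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def make_ground_truth(
    net: MetabolicNetwork,
    elasticity_scale: float = 1.0,
    fluct_scale: float = 0.1,
    seed: int = 0,
    max_retries: int = 50,
) -> KineticGroundTruth:
    """Sample positive elasticities on the network pattern until the implied
    Jacobian is Hurwitz-stable, then solve for the analytic covariance.

    Substrate/modifier elasticities are drawn uniform on
    elasticity_scale * [0.5, 1.5]; fluctuation intensities uniform on
    fluct_scale * [0.8, 1.2].  Same seed, same truth.
    """
    pattern = net.elasticity_pattern
    if not pattern.any():
        raise ValueError("network has an empty elasticity pattern")
    rng = np.random.default_rng(seed)
    s = net.stoichiometry.astype(float)
    for _ in range(max_retries):
        e = np.zeros_like(pattern, dtype=float)
        e[pattern] = elasticity_scale * rng.uniform(0.5, 1.5, size=int(pattern.sum()))
        jac = s @ e
        if stability_report(jac).stable:
            break
    else:
        raise RuntimeError(
            f"no Hurwitz-stable Jacobian found in {max_retries} elasticity draws"
        )
    flu = np.diag(fluct_scale * rng.uniform(0.8, 1.2, size=net.n_metabolites))
    cov = solve_lyapunov_forward(jac, flu)
    return KineticGroundTruth(network=net, elasticities=e, jacobian=jac, fluctuation=flu, covariance=cov)


def perturb_condition(
    truth: KineticGroundTruth, reaction: str, metabolite: str, factor: float
) -> KineticGroundTruth:
    """Knockout-like condition: scale one reaction elasticity by ``factor``
    and recompute Jacobian and analytic covariance."""
    net = truth.network
    try:
        p = net.reaction_ids.index(reaction)
    except ValueError:
        raise KeyError(f"unknown reaction {reaction!r}") from None
    q = net.metabolite_index(metabolite)
    if not net.elasticity_pattern[p, q]:
        raise ValueError(
            f"({reaction}, {metabolite}) is not on the elasticity pattern; nothing to perturb"
        )
    e = truth.elasticities.copy()
    e[p, q] *= factor
    jac = net.stoichiometry.astype(float) @ e
    if not stability_report(jac).stable:
        raise RuntimeError(f"perturbation ({reaction}, {metabolite}) x{factor} destabilizes the system")
    cov = solve_lyapunov_forward(jac, truth.fluctuation)
    return KineticGroundTruth(
        network=net, elasticities=e, jacobian=jac, fluctuation=truth.fluctuation, covariance=cov
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Euler-Maruyama sampling design for one condition.

    ``dt``, ``burn_in`` and ``thinning`` default to automatic choices based
    on the system's time scales: dt = safety/spectral-radius (with the hard
    guard dt * max|eigenvalue| < 0.1), burn-in covering ten relaxation times
    and thinning about two, so consecutive samples are nearly independent.
    ``offset_in_sd`` sets each metabolite's steady-state mean in units of its
    stationary SD (default 10, keeping intensities positive without touching
    the covariance).
    """

    n_samples: int = 6
    dt: float | None = None
    burn_in: int | None = None
    thinning: int | None = None
    measurement_noise_sd: float = 0.0
    offset_in_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")


def _resolve_timestep(truth: KineticGroundTruth, config: SimulationConfig) -> tuple[float, int, int]:
    eig = np.linalg.eigvals(truth.jacobian)
    rho = float(np.abs(eig).max())
    slowest = float(-eig.real.max())  # slowest relaxation rate
    dt = config.dt if config.dt is not None else 0.05 / rho
    if dt * rho >= 0.1:
        raise ValueError(
            f"dt={dt:g} too large for stability: dt * max|eigenvalue| = {dt * rho:.3f} >= 0.1"
        )
    burn_in = config.burn_in if config.burn_in is not None else math.ceil(10.0 / (slowest * dt))
    thinning = config.thinning if config.thinning is not None else math.ceil(2.0 / (slowest * dt))
    if burn_in < 1 or thinning < 1:
        raise ValueError("burn_in and thinning must be positive")
    return dt, burn_in, thinning


def simulate_ou(
    truth: KineticGroundTruth,
    config: SimulationConfig,
    condition_label: str = "control",
    rng: np.random.Generator | None = None,
) -> ProfileMatrix:
    """Simulate replicate metabolite profiles from the linear Langevin model.

    Euler-Maruyama steps x <- x + dt J x + sqrt(2 dt) sqrt(F) z are run for a
    burn-in, then one sample is emitted every ``thinning`` steps.  Stationary
    offsets (mean = offset_in_sd x stationary SD per metabolite) are added so
    all emitted intensities are positive; optional i.i.d. Gaussian
    measurement noise is applied last.
    """
    if not stability_report(truth.jacobian).stable:
        raise ValueError("ground truth Jacobian is not stable; no stationary regime to simulate")
    dt, burn_in, thinning = _resolve_timestep(truth, config)
    n = truth.network.n_metabolites
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noise_amp = np.sqrt(2.0 * dt * np.diag(truth.fluctuation))
    jac = truth.jacobian
    x = np.zeros(n)
    samples = np.empty((config.n_samples, n))
    total_steps = burn_in + config.n_samples * thinning
    k = 0
    for step in range(1, total_steps + 1):
        x = x + dt * (jac @ x) + noise_amp * rng.standard_normal(n)
        if step > burn_in and (step - burn_in) % thinning == 0:
            samples[k] = x
            k += 1
    offsets = config.offset_in_sd * truth.stationary_sd
    values = samples + offsets
    if config.measurement_noise_sd > 0:
        values = values + config.measurement_noise_sd * rng.standard_normal(values.shape)
    if np.any(values <= 0):
        raise ValueError(
            "simulated intensities went non-positive; increase offset_in_sd"
        )
    ids = truth.network.metabolite_ids
    return ProfileMatrix(
        values=values,
        metabolite_ids=ids,
        sample_ids=[f"{condition_label}_{i + 1}" for i in range(config.n_samples)],
        condition=[condition_label] * config.n_samples,
    )


def generate_two_condition_dataset(
    truth: KineticGroundTruth,
    perturbation: tuple[str, str, float],
    config: SimulationConfig,
    condition_labels: tuple[str, str] = ("control", "knockout"),
) -> tuple[ProfileMatrix, ProfileMatrix, tuple[KineticGroundTruth, KineticGroundTruth]]:
    """Paired control/perturbed simulation with disjoint seed substreams.

    ``perturbation`` is (reaction id, metabolite id, factor) applied to the
    control truth to obtain the knockout-like condition.
    """
    rxn, met, factor = perturbation
    perturbed = perturb_condition(truth, rxn, met, factor)
    rng_a = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    rng_b = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    prof_a = simulate_ou(truth, config, condition_label=condition_labels[0], rng=rng_a)
    prof_b = simulate_ou(perturbed, config, condition_label=condition_labels[1], rng=rng_b)
    return prof_a, prof_b, (truth, perturbed)
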