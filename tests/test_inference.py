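import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metarecon.inference import (
    FluctuationModel,
    InverseProblem,
    ensemble_invert,
    invert_once,
    sample_fluctuation,
    solve_lyapunov_forward,
    stability_report,
)
from metarecon.network import parse_network
from metarecon.profiles import CovarianceMatrix
from metarecon.synthetic import make_ground_truth, random_network

from conftest import lyapunov_vectorized_oracle, random_stable_jacobian


# ---------------------------------------------------------------------------
# forward solver
# ---------------------------------------------------------------------------


def test_forward_scalar_and_diagonal_cases():
    assert solve_lyapunov_forward(np.array([[-1.0]]), np.array([[1.0]]))[0, 0] == pytest.approx(1.0)
    c = solve_lyapunov_forward(np.diag([-1.0, -2.0]), np.eye(2))
    assert np.allclose(np.diag(c), [1.0, 0.5])


def test_forward_residual_small_on_random_stable_system(rng):
    jac = random_stable_jacobian(6, rng)
    flu = np.eye(6)
    c = solve_lyapunov_forward(jac, flu)
    resid = np.linalg.norm(jac @ c + c @ jac.T + 2 * flu)
    assert resid <= 1e-10 * (1 + np.linalg.norm(c))


def test_forward_agrees_with_vectorized_oracle(rng):
    for n in (2, 4, 6):
        jac = random_stable_jacobian(n, rng)
        d = np.diag(rng.uniform(0.5, 2.0, size=n))
        c = solve_lyapunov_forward(jac, d)
        assert np.allclose(c, lyapunov_vectorized_oracle(jac, d), atol=1e-10)


def test_forward_rejects_unstable_and_asymmetric(rng):
    with pytest.raises(ValueError, match="non-stable"):
        solve_lyapunov_forward(np.diag([1.0, -1.0]), np.eye(2))
    flu = np.array([[1.0, 0.5], [0.0, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        solve_lyapunov_forward(np.diag([-1.0, -2.0]), flu)


def test_stability_report_flags():
    assert stability_report(np.diag([-1.0, -2.0])).stable
    assert not stability_report(np.diag([1.0, -1.0])).stable


# ---------------------------------------------------------------------------
# fluctuation sampling
# ---------------------------------------------------------------------------


def test_fluctuation_zero_spread_is_deterministic():
    model = FluctuationModel(base_intensity=np.array([1.0, 2.0]), spread=0.0, seed=3)
    assert np.array_equal(sample_fluctuation(model, 2, 7), np.diag([1.0, 2.0]))


def test_fluctuation_substreams_reproducible():
    model = FluctuationModel(base_intensity=np.ones(3), spread=0.2, seed=11)
    a = sample_fluctuation(model, 3, 5)
    b = sample_fluctuation(model, 3, 5)
    c = sample_fluctuation(model, 3, 6)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_fluctuation_median_is_base():
    model = FluctuationModel(base_intensity=np.ones(2), spread=0.2, seed=0)
    draws = np.stack([np.diag(sample_fluctuation(model, 2, d)) for d in range(10_000)])
    med = np.median(draws, axis=0)
    assert np.all(np.abs(med - 1.0) < 0.02)  # log-normal median equals base


# ---------------------------------------------------------------------------
# single inversion
# ---------------------------------------------------------------------------


def test_invert_single_metabolite_self_reaction():
    net = parse_network("deg : X ->\n")
    jac = invert_once(np.array([[1.0]]), np.array([[1.0]]), net, ridge=0)
    assert jac[0, 0] == pytest.approx(-1.0)


def test_forward_inverse_round_trip_serine(serine_net, serine_truth):
    jac = invert_once(serine_truth.covariance, serine_truth.fluctuation, serine_net, ridge=0)
    err = np.linalg.norm(jac - serine_truth.jacobian) / np.linalg.norm(serine_truth.jacobian)
    assert err <= 1e-8


def test_round_trip_direct_mode(serine_net, serine_truth):
    jac = invert_once(
        serine_truth.covariance, serine_truth.fluctuation, serine_net, ridge=0, mode="direct"
    )
    err = np.linalg.norm(jac - serine_truth.jacobian) / np.linalg.norm(serine_truth.jacobian)
    assert err <= 1e-8


def test_under_determined_warns_but_satisfies_equation(rng):
    # 5 metabolites, each reaction depends on all metabolites: 25 unknowns, 15 equations
    lines = [
        f"r{i} : M{i} -> | modifiers: " + ", ".join(f"M{j}" for j in range(5) if j != i)
        for i in range(5)
    ]
    net = parse_network("\n".join(lines))
    jac_true = -(np.eye(5) + 0.1 * rng.uniform(size=(5, 5)))  # stable, full mask
    flu = np.eye(5)
    cov = solve_lyapunov_forward(jac_true, flu)
    with pytest.warns(UserWarning, match="under-determined"):
        jac = invert_once(cov, flu, net, ridge=0, mode="direct")
    resid = np.linalg.norm(jac @ cov + cov @ jac.T + 2 * flu)
    assert resid <= 1e-8 * (1 + np.linalg.norm(cov))


def test_inversion_scale_invariance(serine_net, serine_truth):
    s = 7.3
    j1 = invert_once(serine_truth.covariance, serine_truth.fluctuation, serine_net, ridge=0)
    j2 = invert_once(s * serine_truth.covariance, s * serine_truth.fluctuation, serine_net, ridge=0)
    assert np.allclose(j1, j2, atol=1e-10)


def test_dimension_mismatch_rejected(serine_net):
    with pytest.raises(ValueError, match="dimension mismatch"):
        invert_once(np.eye(3), np.eye(3), serine_net)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(n=st.integers(min_value=2, max_value=8), seed=st.integers(min_value=0, max_value=10_000))
def test_round_trip_property_random_networks(n, seed):
    """Forward-then-inverse recovers the true Jacobian on random determinate networks."""
    from hypothesis import assume

    from metarecon.inference import system_rank

    net = random_network(n, seed=seed)
    truth = make_ground_truth(net, seed=seed)
    rank, n_free = system_rank(truth.covariance, net)
    assume(rank == n_free)  # skip structurally unidentifiable draws
    jac = invert_once(truth.covariance, truth.fluctuation, net, ridge=0)
    err = np.linalg.norm(jac - truth.jacobian) / np.linalg.norm(truth.jacobian)
    assert err <= 1e-8


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def _problem(truth, n_draws, spread, seed):
    cov = CovarianceMatrix(truth.covariance, 1000, truth.network.metabolite_ids)
    flu = FluctuationModel(np.diag(truth.fluctuation), spread=spread, seed=seed)
    return InverseProblem(cov=cov, network=truth.network, fluctuation=flu, n_draws=n_draws, ridge=0)


def test_ensemble_zero_spread_degenerates(serine_truth):
    ens = ensemble_invert(_problem(serine_truth, 20, 0.0, 5))
    assert np.all(ens.iqr == 0.0)
    assert np.allclose(ens.draws[0], ens.draws[-1])


def test_ensemble_same_seed_bit_identical(serine_truth):
    a = ensemble_invert(_problem(serine_truth, 50, 0.2, 9))
    b = ensemble_invert(_problem(serine_truth, 50, 0.2, 9))
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.median, b.median)
    assert np.array_equal(a.iqr, b.iqr)


def test_ensemble_structure_invariants(serine_truth):
    ens = ensemble_invert(_problem(serine_truth, 100, 0.2, 1))
    off = ~ens.mask
    assert np.all(ens.draws[:, off] == 0.0)  # exact zeros outside sparsity
    assert np.all(ens.iqr >= 0.0)
    q25, q75 = np.percentile(ens.draws, [25, 75], axis=0)
    assert np.all(ens.median >= q25 - 1e-12) and np.all(ens.median <= q75 + 1e-12)


def test_ensemble_median_signs_match_truth(serine_net, serine_truth):
    ens = ensemble_invert(_problem(serine_truth, 1000, 0.2, 4))
    nz = ens.mask
    assert np.all(np.sign(ens.median[nz]) == np.sign(serine_truth.jacobian[nz]))


def test_recovered_jacobian_usually_stable(serine_net):
    from metarecon.profiles import ProfileMatrix, sample_covariance
    from metarecon.synthetic import SimulationConfig, simulate_ou

    stable = 0
    for seed in range(10):
        truth = make_ground_truth(serine_net, seed=0)
        prof = simulate_ou(truth, SimulationConfig(n_samples=800, seed=seed))
        cov = sample_covariance(prof)
        jac = invert_once(cov, truth.fluctuation, serine_net, ridge=0)
        stable += stability_report(jac).stable
    assert stable >= 9
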