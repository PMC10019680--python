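import numpy as np
import pytest

from metarecon.multivariate import (
    discriminant_table,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    fold_change,
    permutation_validate,
    select_discriminant,
    vip_scores,
    welch_pvalues,
)
from metarecon.profiles import ProfileMatrix


def make_profile(values, labels):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ProfileMatrix(values, [f"m{j}" for j in range(p)], [f"s{i}" for i in range(n)], list(labels))


@pytest.fixture
def shifted_data(rng):
    """Two groups of 10, metabolite m2 shifted by 2 SD."""
    x = rng.normal(10.0, 1.0, size=(20, 6))
    x[10:, 2] += 2.0
    return make_profile(x, ["a"] * 10 + ["b"] * 10)


@pytest.fixture
def separable_data(rng):
    """Clearly separated groups: two metabolites shifted by 3 SD."""
    x = rng.normal(10.0, 1.0, size=(20, 6))
    x[10:, 1] += 3.0
    x[10:, 4] += 3.0
    return make_profile(x, ["a"] * 10 + ["b"] * 10)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_full_rank_explains_everything(rng):
    p = make_profile(rng.normal(size=(10, 6)), ["a"] * 5 + ["b"] * 5)
    model = fit_pca(p)
    assert model.r2x_cum == pytest.approx(1.0, abs=1e-10)
    assert np.all(np.diff(model.r2x) >= -1e-12)  # cumulative, non-decreasing


def test_pca_line_data_one_component(rng):
    t = rng.normal(size=12)
    x = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
    model = fit_pca(make_profile(x, ["a"] * 6 + ["b"] * 6), n_components=1, scale="none")
    assert model.r2x[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_matches_eigendecomposition_oracle(rng):
    x = rng.normal(size=(10, 6))
    p = make_profile(x, ["a"] * 5 + ["b"] * 5)
    model = fit_pca(p, scale="none")
    xc = x - x.mean(axis=0)
    evals, evecs = np.linalg.eigh(xc.T @ xc)
    order = np.argsort(evals)[::-1]
    for a in range(model.n_components):
        v = evecs[:, order[a]]
        cos = abs(v @ model.x_loadings[:, a])
        assert cos == pytest.approx(1.0, abs=1e-8)  # match up to sign


def test_pca_rejects_degenerate_data():
    x = np.ones((5, 3))
    with pytest.raises(ValueError, match="degenerate|constant"):
        fit_pca(make_profile(x, ["a"] * 2 + ["b"] * 3), scale="none")


# ---------------------------------------------------------------------------
# PLS-DA / OPLS-DA
# ---------------------------------------------------------------------------


def test_plsda_single_informative_metabolite(rng):
    y = np.array([0.0] * 10 + [1.0] * 10)
    yc = y - y.mean()
    x = rng.normal(size=(20, 4))
    x -= np.outer(yc, yc @ x) / (yc @ yc)  # noise columns carry no class signal
    x[:, 1] = 3.0 * y + 5.0  # response exactly proportional to one metabolite
    model = fit_plsda(make_profile(x, ["a"] * 10 + ["b"] * 10), n_components=1, scale="none")
    assert model.r2y_cum == pytest.approx(1.0, abs=1e-8)


def test_plsda_scores_orthogonal(shifted_data):
    model = fit_plsda(shifted_data, n_components=3)
    t = model.scores
    gram = t.T @ t
    off = gram - np.diag(np.diag(gram))
    assert np.all(np.abs(off) < 1e-8)


def test_plsda_matches_sklearn_weights(shifted_data):
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    from metarecon.multivariate import _apply_scaler, _encode_labels, _fit_scaler

    y, _ = _encode_labels(shifted_data.condition)
    mean, den = _fit_scaler(shifted_data.values, "pareto")
    xs = _apply_scaler(shifted_data.values, mean, den)
    ref = sklearn.PLSRegression(n_components=2, scale=False).fit(xs, y - y.mean())
    model = fit_plsda(shifted_data, n_components=2)
    for a in range(2):
        cos = abs(ref.x_weights_[:, a] @ model.x_weights[:, a])
        assert cos == pytest.approx(1.0, abs=1e-6)


def test_plsda_separable_classes_predictive(separable_data):
    model = fit_plsda(separable_data, n_components=2)
    assert model.q2_cum > 0.5


def test_plsda_rejects_single_class(rng):
    p = make_profile(rng.normal(size=(6, 3)), ["a"] * 6)
    with pytest.raises(ValueError, match="two classes"):
        fit_plsda(p)


def test_oplsda_zero_orthogonal_equals_one_component_plsda(shifted_data):
    opls = fit_oplsda(shifted_data, n_orthogonal=0)
    pls = fit_plsda(shifted_data, n_components=1)
    assert np.allclose(np.abs(opls.scores[:, 0]), np.abs(pls.scores[:, 0]), atol=1e-8)
    assert opls.r2y_cum == pytest.approx(pls.r2y_cum, abs=1e-10)


def test_oplsda_orthogonal_scores_uncorrelated_with_labels(shifted_data):
    model = fit_oplsda(shifted_data, n_orthogonal=2)
    y = np.array([0.0] * 10 + [1.0] * 10)
    yc = y - y.mean()
    for a in range(model.orthogonal_scores.shape[1]):
        assert abs(model.orthogonal_scores[:, a] @ yc) < 1e-8
    # predictive scores also uncorrelated with removed components
    for a in range(model.orthogonal_scores.shape[1]):
        cov = model.scores[:, 0] @ model.orthogonal_scores[:, a]
        norm = np.linalg.norm(model.scores[:, 0]) * np.linalg.norm(model.orthogonal_scores[:, a])
        assert abs(cov) / norm < 1e-6


def test_oplsda_absorbs_structured_nuisance(rng):
    # class signal on m0, strong label-orthogonal nuisance spread across the rest
    y = np.array([0.0] * 12 + [1.0] * 12)
    nuisance = rng.normal(size=24)
    nuisance -= (nuisance @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
    x = rng.normal(size=(24, 8)) * 0.3
    x[:, 0] += 1.5 * y
    x += np.outer(nuisance, rng.uniform(1.0, 2.0, size=8))
    p = make_profile(x + 20.0, ["a"] * 12 + ["b"] * 12)
    opls = fit_oplsda(p, n_orthogonal=1)
    pls = fit_plsda(p, n_components=1)
    assert opls.q2_cum >= pls.q2_cum - 1e-9


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


def test_vip_undefined_for_pca(shifted_data):
    with pytest.raises(ValueError, match="PCA"):
        vip_scores(fit_pca(shifted_data))


def test_vip_equal_weights_all_one(rng):
    # symmetric design: every metabolite identically informative
    y = np.array([0.0] * 8 + [1.0] * 8)
    x = np.tile(3.0 * y[:, None], (1, 4)) + 10.0
    x += rng.normal(scale=1e-6, size=x.shape)  # break exact degeneracy only
    model = fit_plsda(make_profile(x, ["a"] * 8 + ["b"] * 8), n_components=1, scale="none")
    vip = vip_scores(model)
    assert np.allclose(vip.values, 1.0, atol=1e-3)


def test_vip_squared_sums_to_metabolite_count(shifted_data):
    for model in (fit_plsda(shifted_data, n_components=2), fit_oplsda(shifted_data)):
        vip = vip_scores(model)
        assert vip.pow(2).sum() == pytest.approx(len(shifted_data.metabolite_ids), abs=1e-8)


def test_vip_flags_shifted_metabolite_across_seeds():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.normal(10.0, 1.0, size=(20, 6))
        x[10:, 2] += 2.0
        p = make_profile(x, ["a"] * 10 + ["b"] * 10)
        vip = vip_scores(fit_oplsda(p))
        hits += (vip.idxmax() == "m2") and (vip["m2"] > 1.0)
    assert hits >= 9


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------


def test_permutation_reproducible(shifted_data):
    a = permutation_validate(shifted_data, n_permutations=30, seed=4)
    b = permutation_validate(shifted_data, n_permutations=30, seed=4)
    assert np.array_equal(a.permuted_q2, b.permuted_q2)
    assert a.original_q2 == b.original_q2


def test_permutation_separable_data_beats_all_permutations(rng):
    # groups of 20: permutations nearly collinear with the true labels (which
    # would retain real predictive power) are vanishingly rare
    x = rng.normal(10.0, 1.0, size=(40, 6))
    x[20:, 1] += 3.0
    x[20:, 4] += 3.0
    p = make_profile(x, ["a"] * 20 + ["b"] * 20)
    res = permutation_validate(p, n_permutations=100, seed=0)
    assert np.all(res.permuted_q2 < res.original_q2)
    assert res.intercept_ok
    assert res.p_value_q2 == pytest.approx(1 / 101)


def test_permutation_null_original_not_extreme():
    inside = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(16, 5)) + 10.0
        p = make_profile(x, ["a"] * 8 + ["b"] * 8)
        res = permutation_validate(p, n_permutations=60, seed=seed)
        lo, hi = np.percentile(res.permuted_q2, [2.5, 97.5])
        inside += lo <= res.original_q2 <= hi
    assert inside >= 8


# ---------------------------------------------------------------------------
# fold change, t-test, selection
# ---------------------------------------------------------------------------


def test_fold_change_values(rng):
    x = np.ones((8, 2))
    x[4:, 0] = 4.0  # means 1 vs 4, base 2 -> 2
    p = make_profile(x, ["a"] * 4 + ["b"] * 4)
    fc = fold_change(p, base=2.0)
    assert fc.iloc[0] == pytest.approx(2.0)
    assert fc.iloc[1] == pytest.approx(0.0)


def test_fold_change_matches_oracle_and_rejects_nonpositive(rng):
    x = rng.uniform(1.0, 5.0, size=(10, 3))
    labels = ["a"] * 5 + ["b"] * 5
    p = make_profile(x, labels)
    fc = fold_change(p, base=10.0)
    expected = np.log10(x[5:].mean(axis=0) / x[:5].mean(axis=0))
    assert np.allclose(fc.values, expected)
    x2 = x.copy()
    x2[:5, 1] = -x2[:5, 1]
    with pytest.raises(ValueError, match="m1"):
        fold_change(make_profile(x2, labels))


def test_selection_rule_strict_thresholds():
    table = select_discriminant(
        vip=np.array([1.0, 1.2, 1.2, 0.8]),
        p_values=np.array([0.01, 0.04, 0.05, 0.01]),
    )
    assert list(table["selected"]) == [False, True, False, False]


def test_selection_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        select_discriminant(np.ones(3), np.ones(2))


def test_discriminant_table_finds_true_effects(rng):
    x = rng.normal(10.0, 1.0, size=(12, 40))
    for j in (3, 17, 29):
        x[6:, j] += 2.0
    p = ProfileMatrix(x, [f"m{j}" for j in range(40)], [f"s{i}" for i in range(12)], ["a"] * 6 + ["b"] * 6)
    table = discriminant_table(p)
    selected = set(table.index[table["selected"]])
    assert {"m3", "m17", "m29"} <= selected
    assert len(selected - {"m3", "m17", "m29"}) <= 2


def test_welch_pvalues_match_scipy(shifted_data):
    import scipy.stats

    pv = welch_pvalues(shifted_data)
    ref = scipy.stats.ttest_ind(
        shifted_data.values[:10], shifted_data.values[10:], equal_var=False
    ).pvalue
    assert np.allclose(pv.values, ref)
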