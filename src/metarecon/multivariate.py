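"""Multivariate discriminant statistics for two-group metabolite panels.

Implements the standard metabolomics discriminant workflow: Pareto scaling,
PCA overview, PLS-DA / OPLS-DA latent models with R2X/R2Y and cross-validated
Q2, VIP (variable importance on projection) scores, label-permutation
validation of the latent model, per-metabolite fold change, and the
``VIP > 1 and p < 0.05`` discriminant-metabolite rule with a two-tailed
Welch t-test supplying the p-values.

PLS components are computed with the NIPALS/PLS1 recursion (a single class
response), which exposes the per-component weights and explained response
variance the VIP statistic is defined on:

    VIP_j = sqrt( p * sum_a w_ja^2 SSY_a / sum_a SSY_a ),

with p the metabolite count, w_a the unit-norm weight vectors and SSY_a the
response variance captured by component a; by construction sum_j VIP_j^2 = p,
so the mean squared VIP is one and VIP > 1 flags above-average contributors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .profiles import ProfileMatrix

__all__ = [
    "LatentModel",
    "PermutationResult",
    "fit_pca",
    "fit_plsda",
    "fit_oplsda",
    "vip_scores",
    "permutation_validate",
    "fold_change",
    "welch_pvalues",
    "select_discriminant",
    "discriminant_table",
]

ScaleMethod = Literal["pareto", "none"]


# ---------------------------------------------------------------------------
# scaling / label helpers
# ---------------------------------------------------------------------------


def _fit_scaler(x: np.ndarray, method: ScaleMethod) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    if method == "none":
        return mean, np.ones(x.shape[1])
    if method != "pareto":
        raise ValueError(f"unknown scaling {method!r}")
    sd = x.std(axis=0, ddof=1)
    denom = np.sqrt(np.where(sd == 0, 1.0, sd))
    return mean, denom


def _apply_scaler(x: np.ndarray, mean: np.ndarray, denom: np.ndarray) -> np.ndarray:
    return (x - mean) / denom


def _encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, tuple[str, str]]:
    classes: list[str] = []
    for lab in labels:
        if lab not in classes:
            classes.append(lab)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, found {classes}")
    y = np.array([classes.index(lab) for lab in labels], dtype=float)
    counts = [int((y == k).sum()) for k in (0, 1)]
    if min(counts) < 2:
        raise ValueError(f"each class needs >=2 samples, got counts {counts}")
    return y, (classes[0], classes[1])


# ---------------------------------------------------------------------------
# latent models
# ---------------------------------------------------------------------------


@dataclass
class LatentModel:
    """Fitted latent-variable model (PCA, PLS-DA or OPLS-DA)."""

    kind: Literal["pca", "plsda", "oplsda"]
    n_components: int
    scores: np.ndarray  # samples x components (predictive components)
    x_weights: np.ndarray | None  # metabolites x components, unit columns (PLS only)
    x_loadings: np.ndarray
    y_loadings: np.ndarray | None  # per component (PLS only)
    r2x: np.ndarray  # cumulative per component
    r2y: np.ndarray | None
    q2: np.ndarray | None
    ssy: np.ndarray | None  # response variance captured per component
    metabolite_ids: list[str]
    classes: tuple[str, str] | None = None
    orthogonal_scores: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    n_orthogonal: int = 0

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x[-1])

    @property
    def r2y_cum(self) -> float:
        if self.r2y is None:
            raise ValueError("model has no response (PCA)")
        return float(self.r2y[-1])

    @property
    def q2_cum(self) -> float:
        if self.q2 is None:
            raise ValueError("model has no cross-validated Q2")
        return float(self.q2[-1])


def fit_pca(p: ProfileMatrix, n_components: int | None = None, scale: ScaleMethod = "pareto") -> LatentModel:
    """PCA on (Pareto-scaled) profiles; components ordered by explained variance."""
    x = p.values
    n, nmet = x.shape
    max_comp = min(n - 1, nmet)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    mean, denom = _fit_scaler(x, scale)
    xs = _apply_scaler(x, mean, denom)
    total = float((xs**2).sum())
    if total == 0:
        raise ValueError("degenerate data: all samples identical after centering")
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate of each component positive
    for a in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    scores = (u * s)[:, :n_components]
    loadings = vt[:n_components].T
    r2x = np.cumsum(s[:n_components] ** 2) / total
    return LatentModel(
        kind="pca",
        n_components=n_components,
        scores=scores,
        x_weights=None,
        x_loadings=loadings,
        y_loadings=None,
        r2x=r2x,
        r2y=None,
        q2=None,
        ssy=None,
        metabolite_ids=list(p.metabolite_ids),
    )


def _pls1(x: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS/PLS1 recursion for a single centered response.

    Returns unit-norm weights W, scores T, x-loadings P, y-loadings c and the
    residual X after deflation.  For one y-column NIPALS converges in a single
    pass per component: w = X'y / ||X'y||.
    """
    n, p = x.shape
    xr = x.copy()
    yr = y.copy()
    w_cols, t_cols, p_cols, c_vals = [], [], [], []
    for _ in range(n_components):
        w = xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            break  # residual response orthogonal to X — no further components
        w /= norm
        t = xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        c = float(t @ yr) / tt
        pl = xr.T @ t / tt
        xr = xr - np.outer(t, pl)
        yr = yr - t * c
        w_cols.append(w)
        t_cols.append(t)
        p_cols.append(pl)
        c_vals.append(c)
    if not w_cols:
        raise ValueError("no PLS component could be extracted (response orthogonal to data)")
    return (
        np.column_stack(w_cols),
        np.column_stack(t_cols),
        np.column_stack(p_cols),
        np.array(c_vals),
        xr,
    )


def _pls_predict(x_new: np.ndarray, w: np.ndarray, pl: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cumulative predictions (n x A) of a fitted PLS1 model on new scaled data."""
    xr = x_new.copy()
    preds = np.zeros((x_new.shape[0], w.shape[1]))
    acc = np.zeros(x_new.shape[0])
    for a in range(w.shape[1]):
        t = xr @ w[:, a]
        xr = xr - np.outer(t, pl[:, a])
        acc = acc + t * c[a]
        preds[:, a] = acc
    return preds


def _opls_filter(x: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Remove label-orthogonal variation (orthogonal signal correction).

    Each pass extracts the part of the x-loading orthogonal to the predictive
    weight direction and deflates it from X.
    """
    xr = x.copy()
    w = xr.T @ y
    w /= np.linalg.norm(w)
    t_o, p_o, w_o = [], [], []
    for _ in range(n_orthogonal):
        t = xr @ w
        pl = xr.T @ t / float(t @ t)
        wo = pl - float(w @ pl) * w
        nwo = np.linalg.norm(wo)
        if nwo < 1e-12:
            break  # nothing orthogonal left to remove
        wo /= nwo
        to = xr @ wo
        po = xr.T @ to / float(to @ to)
        xr = xr - np.outer(to, po)
        t_o.append(to)
        p_o.append(po)
        w_o.append(wo)
    t_mat = np.column_stack(t_o) if t_o else np.zeros((x.shape[0], 0))
    p_mat = np.column_stack(p_o) if p_o else np.zeros((x.shape[1], 0))
    w_mat = np.column_stack(w_o) if w_o else np.zeros((x.shape[1], 0))
    return xr, t_mat, p_mat, w_mat


def _cv_folds(y: np.ndarray, cv_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified folds; falls back to leave-one-out when a
    class is smaller than the fold count."""
    n = y.size
    counts = [int((y == k).sum()) for k in (0, 1)]
    if cv_folds > min(counts):
        return [np.array([i]) for i in range(n)]
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(cv_folds)]
    for k in (0, 1):
        idx = np.nonzero(y == k)[0]
        idx = idx[rng.permutation(idx.size)]
        for pos, i in enumerate(idx):
            folds[pos % cv_folds].append(int(i))
    return [np.sort(np.array(f)) for f in folds if f]


def _cv_press(
    x_raw: np.ndarray,
    y01: np.ndarray,
    n_components: int,
    cv_folds: int,
    seed: int,
    scale: ScaleMethod,
    n_orthogonal: int | None = None,
) -> np.ndarray:
    """Cumulative Q2 per component from cross-validated PRESS."""
    folds = _cv_folds(y01, cv_folds, seed)
    press = np.zeros(n_components)
    ss = 0.0
    for test in folds:
        train = np.setdiff1d(np.arange(y01.size), test)
        mean, denom = _fit_scaler(x_raw[train], scale)
        xt = _apply_scaler(x_raw[train], mean, denom)
        y_mean = y01[train].mean()
        yt = y01[train] - y_mean
        xv = _apply_scaler(x_raw[test], mean, denom)
        yv = y01[test] - y_mean
        if n_orthogonal is None:
            w, t, pl, c, _ = _pls1(xt, yt, n_components)
            preds = _pls_predict(xv, w, pl, c)
        else:
            xr, t_o, p_o, w_o = _opls_filter(xt, yt, n_orthogonal)
            for a in range(w_o.shape[1]):
                to = xv @ w_o[:, a]
                xv = xv - np.outer(to, p_o[:, a])
            w, t, pl, c, _ = _pls1(xr, yt, 1)
            preds = _pls_predict(xv, w, pl, c)
        ncomp_eff = preds.shape[1]
        for a in range(n_components):
            resid = yv - preds[:, min(a, ncomp_eff - 1)]
            press[a] += float(resid @ resid)
        ss += float(yv @ yv)
    return 1.0 - press / ss


def fit_plsda(
    p: ProfileMatrix,
    labels: Sequence[str] | None = None,
    n_components: int = 2,
    cv_folds: int = 7,
    scale: ScaleMethod = "pareto",
    cv_seed: int = 0,
) -> LatentModel:
    """Two-class PLS-DA with NIPALS components on Pareto-scaled data.

    R2Y is the fitted fraction of (centered 0/1) class-response variance;
    Q2 the cross-validated analogue from stratified k-fold PRESS (leave-one-
    out when a class is smaller than the fold count).
    """
    if labels is None:
        labels = p.condition
    y01, classes = _encode_labels(labels)
    x_raw = p.values
    mean, denom = _fit_scaler(x_raw, scale)
    xs = _apply_scaler(x_raw, mean, denom)
    y = y01 - y01.mean()
    w, t, pl, c, x_resid = _pls1(xs, y, n_components)
    a_eff = w.shape[1]
    total_x = float((xs**2).sum())
    r2x = np.empty(a_eff)
    r2y = np.empty(a_eff)
    ssy = np.empty(a_eff)
    ssy_total = float(y @ y)
    yr = y.copy()
    xsr = xs.copy()
    for a in range(a_eff):
        xsr = xsr - np.outer(t[:, a], pl[:, a])
        yr = yr - t[:, a] * c[a]
        r2x[a] = 1.0 - float((xsr**2).sum()) / total_x
        r2y[a] = 1.0 - float(yr @ yr) / ssy_total
        ssy[a] = c[a] ** 2 * float(t[:, a] @ t[:, a])
    q2 = _cv_press(x_raw, y01, a_eff, cv_folds, cv_seed, scale)
    return LatentModel(
        kind="plsda",
        n_components=a_eff,
        scores=t,
        x_weights=w,
        x_loadings=pl,
        y_loadings=c,
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        ssy=ssy,
        metabolite_ids=list(p.metabolite_ids),
        classes=classes,
    )


def fit_oplsda(
    p: ProfileMatrix,
    labels: Sequence[str] | None = None,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    scale: ScaleMethod = "pareto",
    cv_seed: int = 0,
) -> LatentModel:
    """OPLS-DA: strip label-orthogonal components, then fit one predictive
    PLS component.  ``n_orthogonal=0`` reduces to 1-component PLS-DA."""
    if labels is None:
        labels = p.condition
    y01, classes = _encode_labels(labels)
    x_raw = p.values
    mean, denom = _fit_scaler(x_raw, scale)
    xs = _apply_scaler(x_raw, mean, denom)
    y = y01 - y01.mean()
    total_x = float((xs**2).sum())
    xr, t_o, p_o, w_o = _opls_filter(xs, y, n_orthogonal)
    w, t, pl, c, x_resid = _pls1(xr, y, 1)
    ssy_total = float(y @ y)
    yr = y - t[:, 0] * c[0]
    r2y = np.array([1.0 - float(yr @ yr) / ssy_total])
    explained = total_x - float(((xr - np.outer(t[:, 0], pl[:, 0])) ** 2).sum())
    r2x = np.array([explained / total_x])
    ssy = np.array([c[0] ** 2 * float(t[:, 0] @ t[:, 0])])
    q2 = _cv_press(x_raw, y01, 1, cv_folds, cv_seed, scale, n_orthogonal=n_orthogonal)
    return LatentModel(
        kind="oplsda",
        n_components=1,
        scores=t,
        x_weights=w,
        x_loadings=pl,
        y_loadings=c,
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        ssy=ssy,
        metabolite_ids=list(p.metabolite_ids),
        classes=classes,
        orthogonal_scores=t_o,
        orthogonal_loadings=p_o,
        n_orthogonal=t_o.shape[1],
    )


def vip_scores(model: LatentModel) -> pd.Series:
    """VIP per metabolite; squared scores sum to the metabolite count."""
    if model.kind == "pca":
        raise ValueError("VIP undefined for PCA (no response to project on)")
    assert model.x_weights is not None and model.ssy is not None
    w2 = model.x_weights**2  # columns already unit norm
    weights = model.ssy / model.ssy.sum()
    p = len(model.metabolite_ids)
    vip = np.sqrt(p * (w2 @ weights))
    return pd.Series(vip, index=model.metabolite_ids, name="vip")


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Label-permutation check of latent-model validity.

    ``intercept_ok`` applies the intercept criterion: regressing permuted
    R2/Q2 against the correlation between permuted and original labels, both
    intercepts (the expected performance of a fully scrambled model) must lie
    below the original model's R2 and Q2.
    """

    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    label_correlations: np.ndarray
    original_r2: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float

    @property
    def intercept_ok(self) -> bool:
        return self.r2_intercept < self.original_r2 and self.q2_intercept < self.original_q2

    @property
    def p_value_q2(self) -> float:
        """Add-one empirical p-value of the original Q2 against the permuted distribution."""
        exceed = int(np.sum(self.permuted_q2 >= self.original_q2))
        return (1 + exceed) / (self.n_permutations + 1)


def permutation_validate(
    p: ProfileMatrix,
    labels: Sequence[str] | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    n_components: int = 2,
    cv_folds: int = 7,
    method: Literal["plsda", "oplsda"] = "plsda",
    scale: ScaleMethod = "pareto",
) -> PermutationResult:
    """Refit the discriminant model on label-permuted data n times and compare
    R2Y/Q2 distributions with the original model."""
    if labels is None:
        labels = p.condition
    y01, classes = _encode_labels(labels)

    def _fit(lab: Sequence[str]) -> tuple[float, float]:
        if method == "plsda":
            m = fit_plsda(p, lab, n_components=n_components, cv_folds=cv_folds, scale=scale, cv_seed=seed)
        else:
            m = fit_oplsda(p, lab, n_orthogonal=max(n_components - 1, 0), cv_folds=cv_folds, scale=scale, cv_seed=seed)
        return m.r2y_cum, m.q2_cum

    orig_r2, orig_q2 = _fit(list(labels))
    rng = np.random.default_rng(seed)
    labels_arr = np.asarray(labels)
    r2s, q2s, cors = [], [], []
    y_c = y01 - y01.mean()
    for _ in range(n_permutations):
        perm = rng.permutation(labels_arr.size)
        perm_labels = labels_arr[perm]
        try:
            r2, q2 = _fit(list(perm_labels))
        except ValueError:
            r2, q2 = 0.0, 0.0  # degenerate permutation (no component extractable)
        yp = y01[perm] - y01.mean()
        denom = float(np.sqrt((y_c @ y_c) * (yp @ yp)))
        cors.append(abs(float(y_c @ yp)) / denom if denom > 0 else 0.0)
        r2s.append(r2)
        q2s.append(q2)
    cors_arr = np.array(cors)
    xs = np.concatenate([cors_arr, [1.0]])
    r2_line = np.polyfit(xs, np.concatenate([r2s, [orig_r2]]), 1)
    q2_line = np.polyfit(xs, np.concatenate([q2s, [orig_q2]]), 1)
    return PermutationResult(
        n_permutations=n_permutations,
        permuted_r2=np.array(r2s),
        permuted_q2=np.array(q2s),
        label_correlations=cors_arr,
        original_r2=orig_r2,
        original_q2=orig_q2,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
    )


# ---------------------------------------------------------------------------
# univariate statistics and selection
# ---------------------------------------------------------------------------


def fold_change(
    p: ProfileMatrix, labels: Sequence[str] | None = None, base: float = 2.0
) -> pd.Series:
    """Per metabolite, log_base of the ratio of class mean intensities
    (second class over first, in label first-appearance order)."""
    if labels is None:
        labels = p.condition
    y01, classes = _encode_labels(labels)
    m1 = p.values[y01 == 0].mean(axis=0)
    m2 = p.values[y01 == 1].mean(axis=0)
    bad = (m1 <= 0) | (m2 <= 0)
    if bad.any():
        names = [p.metabolite_ids[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"non-positive class mean for metabolite(s) {names}")
    fc = np.log(m2 / m1) / np.log(base)
    return pd.Series(fc, index=p.metabolite_ids, name=f"log{base:g}_fold_change_{classes[1]}_vs_{classes[0]}")


def welch_pvalues(p: ProfileMatrix, labels: Sequence[str] | None = None, equal_var: bool = False) -> pd.Series:
    """Two-tailed two-sample t-test p-value per metabolite (Welch by default)."""
    if labels is None:
        labels = p.condition
    y01, _ = _encode_labels(labels)
    res = scipy.stats.ttest_ind(p.values[y01 == 0], p.values[y01 == 1], equal_var=equal_var, axis=0)
    return pd.Series(res.pvalue, index=p.metabolite_ids, name="p_value")


def select_discriminant(
    vip: pd.Series | np.ndarray,
    p_values: pd.Series | np.ndarray,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    log_fold_change: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Discriminant-metabolite table: selected iff VIP > threshold (strict)
    and p < alpha (strict)."""
    vip_arr = np.asarray(vip, dtype=float)
    p_arr = np.asarray(p_values, dtype=float)
    if vip_arr.shape != p_arr.shape:
        raise ValueError("vip and p_values length mismatch")
    index = vip.index if isinstance(vip, pd.Series) else pd.RangeIndex(vip_arr.size)
    table = pd.DataFrame({"vip": vip_arr, "p_value": p_arr}, index=index)
    if log_fold_change is not None:
        table["log_fold_change"] = np.asarray(log_fold_change, dtype=float)
    table["selected"] = (vip_arr > vip_threshold) & (p_arr < alpha)
    return table


def discriminant_table(
    p: ProfileMatrix,
    labels: Sequence[str] | None = None,
    n_orthogonal: int = 1,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    fc_base: float = 2.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """One-call discriminant workflow: OPLS-DA VIP + Welch t-test + fold change."""
    if labels is None:
        labels = p.condition
    model = fit_oplsda(p, labels, n_orthogonal=n_orthogonal)
    vip = vip_scores(model)
    pv = welch_pvalues(p, labels, equal_var=equal_var)
    fc = fold_change(p, labels, base=fc_base)
    return select_discriminant(vip, pv, vip_threshold, alpha, log_fold_change=fc)
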