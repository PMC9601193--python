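"""Orthogonal PLS discriminant analysis for two-group metabolomics tables.

OPLS-DA splits the (scaled) data matrix X into variation correlated with
the class vector y and variation orthogonal to it. Orthogonal components
are extracted and deflated first; a single predictive component is then fit
on the deflated matrix, so the predictive scores t carry all of the
between-class separation and each orthogonal score vector is exactly
orthogonal to t. The fit is deterministic: for a single response the PLS
weight vector has the closed form w ∝ Xᵀy and no iteration is needed.

Model quality is summarised by R²X (X-variance captured by all
components), R²Y (class variance explained in training) and Q² (class
variance predicted under k-fold cross-validation); Q² under label
permutation calibrates the null. Per-sample diagnostics are DModX
(normalised X-residual distance, F-test critical value) and Hotelling's T²
over the model scores (exact training-set beta-distribution ellipse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peaks import PeakTable

__all__ = [
    "OplsModel",
    "VipResult",
    "PermutationResult",
    "OutlierReport",
    "fit_opls_da",
    "select_n_orthogonal",
    "vip_scores",
    "outlier_report",
    "remove_outliers_and_refit",
    "permutation_test",
]

_RANK_TOL = 1e-12


@dataclass(frozen=True)
class OplsModel:
    """Fitted OPLS-DA decomposition (one predictive + k orthogonal components)."""

    weights: np.ndarray          # predictive weight vector w (unit norm)
    loadings: np.ndarray         # predictive X-loading p
    scores: np.ndarray           # predictive score vector t (n samples)
    y_loading: float             # c, regression of centered y on t
    ortho_weights: np.ndarray    # (k, p) orthogonal weights W_o
    ortho_loadings: np.ndarray   # (k, p) orthogonal loadings P_o
    ortho_scores: np.ndarray     # (n, k) orthogonal scores T_o
    center: np.ndarray           # per-variable centering vector
    scale: np.ndarray            # per-variable scaling vector
    y_mean: float
    scaling: str
    r2x: float
    r2y: float
    q2: float | None = None
    residuals: np.ndarray = field(repr=False, default=None)  # scaled-space E

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_weights.shape[0]

    @property
    def n_components(self) -> int:
        return 1 + self.n_orthogonal

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project new rows: returns (predictive scores, orthogonal scores)."""
        xs = (np.asarray(x, dtype=float) - self.center) / self.scale
        t_o = np.zeros((xs.shape[0], self.n_orthogonal))
        for a in range(self.n_orthogonal):
            t_o[:, a] = xs @ self.ortho_weights[a]
            xs = xs - np.outer(t_o[:, a], self.ortho_loadings[a])
        return xs @ self.weights, t_o

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class value for new rows."""
        t, _ = self.transform(x)
        return t * self.y_loading + self.y_mean


@dataclass(frozen=True)
class VipResult:
    """Variable importance in projection, one score per metabolite."""

    metabolite_ids: list[str]
    vip: np.ndarray
    threshold: float = 0.75

    def selected(self) -> list[str]:
        """Metabolites with VIP strictly above the threshold."""
        return [m for m, v in zip(self.metabolite_ids, self.vip) if v > self.threshold]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.metabolite_ids, map(float, self.vip)))


@dataclass(frozen=True)
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    n_permutations: int

    @property
    def p_value_q2(self) -> float:
        n_ge = int(np.sum(self.permuted_q2 >= self.observed_q2))
        return (1 + n_ge) / (self.n_permutations + 1)


@dataclass(frozen=True)
class OutlierReport:
    sample_ids: list[str]
    dmodx: np.ndarray
    dmodx_critical: float
    t2: np.ndarray
    t2_critical: float
    flagged: list[tuple[str, str]]  # (sample id, criterion)

    @property
    def flagged_ids(self) -> list[str]:
        return [s for s, _ in self.flagged]


def _scale_matrix(x: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if scaling == "unit_variance":
        scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "center_only":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (x - center) / scale, center, scale


def _check_inputs(table: PeakTable, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = table.areas.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("peak table contains missing values; drop or impute before fitting")
    y = np.asarray(labels, dtype=float).ravel()
    if y.size != x.shape[0]:
        raise ValueError("labels length does not match number of samples")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"labels must contain exactly two classes, got {classes.size}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return x, y


def _fit_arrays(
    x_raw: np.ndarray, y: np.ndarray, n_orthogonal: int, scaling: str
) -> OplsModel:
    """Numpy-only fitting core shared by the public fit and cross-validation."""
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    x, center, scale = _scale_matrix(x_raw, scaling)
    y_mean = y.mean()
    yc = y - y_mean
    ssx_total = float(np.sum(x**2))
    ssy_total = float(np.sum(yc**2))

    xd = x.copy()
    w_o_list, p_o_list, t_o_list = [], [], []
    for _ in range(n_orthogonal):
        w = xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < _RANK_TOL:
            raise ValueError("X carries no y-covariance; cannot extract component")
        w /= nw
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-8 * max(np.linalg.norm(p), 1.0):
            raise ValueError(
                "requested more orthogonal components than the data rank supports"
            )
        w_o /= n_wo
        t_o = xd @ w_o
        tt_o = t_o @ t_o
        if tt_o < _RANK_TOL:
            raise ValueError(
                "requested more orthogonal components than the data rank supports"
            )
        p_o = xd.T @ t_o / tt_o
        xd = xd - np.outer(t_o, p_o)
        w_o_list.append(w_o)
        p_o_list.append(p_o)
        t_o_list.append(t_o)

    w = xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < _RANK_TOL:
        raise ValueError("no predictive covariance left after orthogonal deflation")
    w /= nw
    t = xd @ w
    tt = t @ t
    p = xd.T @ t / tt
    c = float(t @ yc / tt)
    residuals = xd - np.outer(t, p)

    r2x = 1.0 - float(np.sum(residuals**2)) / ssx_total if ssx_total > 0 else 0.0
    r2y = 1.0 - float(np.sum((yc - c * t) ** 2)) / ssy_total

    k = len(w_o_list)
    p_vars = x.shape[1]
    return OplsModel(
        weights=w,
        loadings=p,
        scores=t,
        y_loading=c,
        ortho_weights=np.array(w_o_list).reshape(k, p_vars),
        ortho_loadings=np.array(p_o_list).reshape(k, p_vars),
        ortho_scores=(np.column_stack(t_o_list) if k else np.zeros((x.shape[0], 0))),
        center=center,
        scale=scale,
        y_mean=y_mean,
        scaling=scaling,
        r2x=r2x,
        r2y=r2y,
        residuals=residuals,
    )


def fit_opls_da(
    table: PeakTable,
    labels: np.ndarray,
    n_orthogonal: int = 0,
    scaling: str = "unit_variance",
) -> OplsModel:
    """Fit a deterministic OPLS-DA model with one predictive component.

    Orthogonal components are extracted and removed from X first (each is,
    by construction, exactly orthogonal to the class-predictive scores that
    follow); with ``n_orthogonal=0`` the fit is a plain one-component
    PLS-DA of the scaled data.
    """
    x_raw, y = _check_inputs(table, labels)
    return _fit_arrays(x_raw, y, n_orthogonal, scaling)


def _fold_assignment(n: int, cv_folds: int, seed: int | None) -> np.ndarray:
    """Venetian-blind folds over a seeded sample ordering."""
    order = (
        np.random.default_rng(seed).permutation(n) if seed is not None else np.arange(n)
    )
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % cv_folds
    return folds


def cross_validated_q2(
    table: PeakTable,
    labels: np.ndarray,
    n_orthogonal: int = 0,
    cv_folds: int = 7,
    seed: int | None = 0,
    scaling: str = "unit_variance",
) -> float:
    """Q²: 1 − PRESS/SS of the class vector under k-fold cross-validation."""
    x, y = _check_inputs(table, labels)
    return _cv_q2_arrays(x, y, n_orthogonal, cv_folds, seed, scaling)


def _cv_q2_arrays(
    x: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int,
    cv_folds: int,
    seed: int | None,
    scaling: str,
) -> float:
    n = x.shape[0]
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if cv_folds > n:
        raise ValueError(f"cv_folds={cv_folds} exceeds the {n} available samples")
    folds = _fold_assignment(n, cv_folds, seed)
    press = 0.0
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        y_train = y[train]
        if np.unique(y_train).size < 2:
            # degenerate fold: predict the training mean
            press += float(np.sum((y[test] - y_train.mean()) ** 2))
            continue
        model = _fit_arrays(x[train], y_train, n_orthogonal, scaling)
        y_hat = model.predict(x[test])
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def select_n_orthogonal(
    table: PeakTable,
    labels: np.ndarray,
    max_k: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
    scaling: str = "unit_variance",
    tolerance: float = 0.01,
) -> int:
    """Smallest number of orthogonal components within ``tolerance`` of the best Q²."""
    if max_k < 0:
        raise ValueError("max_k must be >= 0")
    x, y = _check_inputs(table, labels)
    return _select_k_arrays(x, y, max_k, cv_folds, seed, scaling, tolerance)


def _select_k_arrays(
    x: np.ndarray,
    y: np.ndarray,
    max_k: int,
    cv_folds: int,
    seed: int | None,
    scaling: str,
    tolerance: float = 0.01,
) -> int:
    q2s: list[float] = []
    for k in range(max_k + 1):
        try:
            q2s.append(_cv_q2_arrays(x, y, k, cv_folds, seed, scaling))
        except ValueError:
            if not q2s:
                raise
            break  # rank exhausted
    best = max(q2s)
    for k, q in enumerate(q2s):
        if q >= best - tolerance:
            return k
    return 0  # unreachable


def vip_scores(
    model: OplsModel, table: PeakTable, labels: np.ndarray, threshold: float = 0.75
) -> VipResult:
    """Variable importance in projection for the predictive component.

    With a single predictive component the VIP formula reduces to
    VIP_j = sqrt(p) * |w_j| / ||w||, so the mean squared VIP is exactly 1:
    a variable with VIP > 1 contributes more than an average variable to
    the class separation.
    """
    p_vars = len(model.weights)
    if table.areas.shape[1] != p_vars:
        raise ValueError(
            f"model has {p_vars} variables but table has {table.areas.shape[1]}"
        )
    w = model.weights
    vip = np.sqrt(p_vars) * np.abs(w) / np.linalg.norm(w)
    return VipResult(metabolite_ids=table.metabolite_ids, vip=vip, threshold=threshold)


def outlier_report(model: OplsModel, table: PeakTable, alpha: float = 0.05) -> OutlierReport:
    """Flag samples by DModX (X-residual distance) and Hotelling's T² ellipse.

    DModX_i is the per-sample residual standard deviation relative to the
    pooled model residual sd computed with sample i left out (the
    leave-one-out form: a gross outlier would otherwise inflate the very
    reference it is compared against and mask itself); DModX² is referred
    to an F(K−A, (N−A−2)(K−A)) quantile at 1−alpha. T² combines predictive
    and orthogonal scores; because these are *training* scores whose
    variance estimate includes the sample itself, T² is bounded by
    (N−1)²/N and the ellipse radius uses its exact beta distribution,
    (N−1)²/N · Beta(A/2, (N−A−1)/2), rather than the F form that applies
    to new observations (unattainable at small N and strict alpha).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    e = model.residuals
    n, k_vars = e.shape
    a = model.n_components
    df_sample = k_vars - a
    df_total = (n - a - 1) * df_sample
    df_loo = df_total - df_sample
    if df_sample <= 0 or df_loo <= 0:
        raise ValueError("too few variables/samples for residual diagnostics")
    s_i2 = np.sum(e**2, axis=1) / df_sample
    ss_all = float(np.sum(e**2))
    s0_loo2 = (ss_all - df_sample * s_i2) / df_loo
    with np.errstate(divide="ignore", invalid="ignore"):
        dmodx = np.sqrt(np.where(s0_loo2 > 0, s_i2 / s0_loo2, 0.0))
    dcrit = float(np.sqrt(stats.f.ppf(1 - alpha, df_sample, df_loo)))

    scores = np.column_stack([model.scores, model.ortho_scores])
    var = scores.var(axis=0, ddof=1)
    var = np.where(var > 0, var, 1.0)
    t2 = np.sum(scores**2 / var, axis=1)
    if n - a - 1 <= 0:
        raise ValueError("too few samples for a T² ellipse")
    t2_crit = float(
        (n - 1) ** 2 / n * stats.beta.ppf(1 - alpha, a / 2, (n - a - 1) / 2)
    )

    flagged = []
    for i, sid in enumerate(table.sample_ids):
        reasons = []
        if dmodx[i] > dcrit:
            reasons.append("dmodx")
        if t2[i] > t2_crit:
            reasons.append("t2")
        if reasons:
            flagged.append((sid, "+".join(reasons)))
    return OutlierReport(
        sample_ids=table.sample_ids,
        dmodx=dmodx,
        dmodx_critical=dcrit,
        t2=t2,
        t2_critical=t2_crit,
        flagged=flagged,
    )


def remove_outliers_and_refit(
    table: PeakTable,
    labels: np.ndarray,
    alpha: float = 0.001,
    max_rounds: int = 3,
    n_orthogonal: int = 0,
    scaling: str = "unit_variance",
    min_per_class: int = 3,
) -> tuple[PeakTable, OplsModel, OutlierReport]:
    """Iterate fit → flag → drop until clean, bounded by ``max_rounds``.

    Elimination defaults to a much stricter level (alpha 0.001) than the
    diagnostic report: at the 95% level roughly one sample in twenty sits
    outside the ellipse by chance, which is worth inspecting but not
    silently discarding. Never reduces either class below
    ``min_per_class`` samples: a removal that would do so is skipped with
    a warning instead. Raises if the flagged set would empty a class
    outright.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    y = np.asarray(labels).ravel()
    current = table
    for _ in range(max_rounds):
        model = fit_opls_da(current, y, n_orthogonal=n_orthogonal, scaling=scaling)
        report = outlier_report(model, current, alpha=alpha)
        if not report.flagged:
            return current, model, report
        drop = set(report.flagged_ids)
        keep_mask = np.array([s not in drop for s in current.sample_ids])
        for cls in np.unique(y):
            n_left = int(np.sum(keep_mask & (y == cls)))
            if n_left == 0:
                raise ValueError(
                    f"outlier removal would empty class {cls!r}"
                )
            if n_left < min_per_class:
                warnings.warn(
                    f"outlier removal would leave class {cls!r} with {n_left} < "
                    f"{min_per_class} samples; stopping elimination",
                    stacklevel=2,
                )
                return current, model, report
        current = current.subset_samples(
            [s for s, m in zip(current.sample_ids, keep_mask) if m]
        )
        y = y[keep_mask]
    model = fit_opls_da(current, y, n_orthogonal=n_orthogonal, scaling=scaling)
    report = outlier_report(model, current, alpha=alpha)
    return current, model, report


def permutation_test(
    table: PeakTable,
    labels: np.ndarray,
    n_permutations: int = 99,
    seed: int = 0,
    max_k: int = 2,
    cv_folds: int = 7,
    scaling: str = "unit_variance",
) -> PermutationResult:
    """Label-permutation validation of the cross-validated model quality.

    The full pipeline (orthogonal-component selection by CV, then fit and
    Q²) is rerun under each random relabelling; the add-one-corrected
    p-value is the fraction of permutations whose Q² reaches the observed
    one.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a p <= 0.05 resolution")
    x, y = _check_inputs(table, labels)
    rng = np.random.default_rng(seed)

    def _pipeline(yy: np.ndarray) -> tuple[float, float]:
        k = _select_k_arrays(x, yy, max_k, cv_folds, seed, scaling)
        model = _fit_arrays(x, yy, k, scaling)
        q2 = _cv_q2_arrays(x, yy, k, cv_folds, seed, scaling)
        return model.r2y, q2

    obs_r2y, obs_q2 = _pipeline(y)
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_r2y[i], perm_q2[i] = _pipeline(rng.permutation(y))
    return PermutationResult(
        observed_r2y=obs_r2y,
        observed_q2=obs_q2,
        permuted_r2y=perm_r2y,
        permuted_q2=perm_q2,
        n_permutations=n_permutations,
    )
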