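"""Native latent-variable chemometrics: NIPALS PCA, SIMCA class models, OPLS-DA.

All algorithms are implemented from the linear-algebra primitives up, in the
formulations standard for spectral data:

* PCA by NIPALS with deflation (scores/loadings equal the SVD solution up to
  sign on full-rank data), with cross-validated Q2 = 1 - PRESS/SS;
* SIMCA (PCA-class): one PCA sub-model per class, membership judged by the
  normalized distance to the model (DModX) against an F-quantile threshold;
* OPLS-DA: variation orthogonal to the one-hot class dummy matrix is stripped
  component by component, then a PLS2 model is fitted on the filtered X.
  Quality is tracked as R2X / R2Y / Q2Y, RMSEE / RMSECV / RMSEP, and a
  permutation test with R2Y / Q2Y intercepts.

Mean-centering only is the default scaling, the usual choice for [0, 1]-
normalized absorbance spectra; unit-variance and Pareto scaling are options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evaluation import confusion_matrix, core_metrics, ovr_counts

__all__ = [
    "PcaModel",
    "ClassPcaModel",
    "OplsdaModel",
    "ModelQuality",
    "PermutationResult",
    "fit_pca_nipals",
    "q2_cross_validation",
    "fit_pca_class",
    "classify_pca_class",
    "fit_oplsda",
    "predict_oplsda",
    "permutation_test",
    "rmse_estimation",
]

_SCALINGS = ("center", "uv", "pareto")


def _scale_matrix(x: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (scaled X, column means, column divisors)."""
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}")
    means = x.mean(axis=0)
    xc = x - means
    if scaling == "center":
        divisor = np.ones(x.shape[1])
    else:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        divisor = sd if scaling == "uv" else np.sqrt(sd)
    return xc / divisor, means, divisor


# ---------------------------------------------------------------------------
# PCA (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    """PCA fit: column means/divisors, scores (n x a), loadings (p x a)."""

    means: np.ndarray
    divisors: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    r2x_per_component: np.ndarray
    q2_cumulative: float | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return ((np.atleast_2d(x) - self.means) / self.divisors) @ self.loadings

    def residuals(self, x: np.ndarray) -> np.ndarray:
        xc = (np.atleast_2d(x) - self.means) / self.divisors
        return xc - (xc @ self.loadings) @ self.loadings.T


def fit_pca_nipals(
    x: np.ndarray,
    n_components: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
    scaling: str = "center",
) -> PcaModel:
    """PCA by NIPALS with deflation.

    Components are extracted one at a time: iterate p = X't/(t't) (normalized)
    and t = Xp until the score vector stabilizes, then deflate X by t p'.
    On full-rank matrices the result matches the SVD solution up to sign.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= min(n-1, p) = {min(n - 1, p)}")
    work, means, divisors = _scale_matrix(x, scaling)
    tss = float(np.sum(work**2))
    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    r2x = np.zeros(n_components)
    for a in range(n_components):
        col_var = np.sum(work**2, axis=0)
        t = work[:, int(np.argmax(col_var))].copy()
        if np.allclose(t, 0):
            # exactly rank-deficient: remaining components carry no variance
            break
        for _ in range(max_iter):
            pa = work.T @ t / (t @ t)
            pa /= np.linalg.norm(pa)
            t_new = work @ pa
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        scores[:, a] = t
        loadings[:, a] = pa
        r2x[a] = float(t @ t) / tss if tss > 0 else 0.0
        work = work - np.outer(t, pa)
    return PcaModel(means=means, divisors=divisors, scores=scores, loadings=loadings, r2x_per_component=r2x)


def q2_cross_validation(
    x: np.ndarray,
    n_folds: int = 7,
    component_range: range | list[int] | None = None,
    seed: int = 0,
    scaling: str = "center",
) -> dict[int, float]:
    """Cumulative PCA Q2 per component count, Q2 = 1 - PRESS/SS.

    Samples are assigned to folds venetian-blind style after a seeded shuffle;
    for each fold a PCA is fitted on the remainder and the held-out spectra
    are reconstructed from their projections.  SS is the centered sum of
    squares of the held-out samples (train-fold means).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError("fold with < 1 sample")
    if component_range is None:
        component_range = range(1, min(n - 1, x.shape[1], 5) + 1)
    order = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds

    results: dict[int, float] = {}
    for n_comp in component_range:
        press = 0.0
        ss = 0.0
        for fold in range(n_folds):
            test = fold_of == fold
            train = ~test
            if train.sum() <= n_comp:
                raise ValueError("training fold too small for requested components")
            model = fit_pca_nipals(x[train], n_components=n_comp, scaling=scaling)
            xc = (x[test] - model.means) / model.divisors
            resid = xc - (xc @ model.loadings) @ model.loadings.T
            press += float(np.sum(resid**2))
            ss += float(np.sum(xc**2))
        results[int(n_comp)] = 1.0 - press / ss if ss > 0 else float("nan")
    return results


# ---------------------------------------------------------------------------
# PCA-class (SIMCA)
# ---------------------------------------------------------------------------


@dataclass
class ClassPcaModel:
    """Per-class PCA sub-models with DModX critical thresholds (SIMCA)."""

    submodels: dict[str, PcaModel]
    s0: dict[str, float]
    dmodx_critical: dict[str, float]
    alpha: float
    class_order: tuple[str, ...]


def _dmodx_s0(model: PcaModel, x_train: np.ndarray) -> float:
    """Pooled residual standard deviation of the training set."""
    e = model.residuals(x_train)
    n, p = e.shape
    a = model.n_components
    dof = max((n - a - 1) * (p - a), 1)
    return float(np.sqrt(np.sum(e**2) / dof))


def fit_pca_class(
    class_matrices: dict[str, np.ndarray],
    n_components: int = 2,
    alpha: float = 0.05,
    scaling: str = "center",
) -> ClassPcaModel:
    """Fit one PCA per class and derive DModX critical limits.

    Every class uses the same component count (default 2, capped at the class
    rank): equal counts keep the normalized distances comparable across
    submodels, which matters for the forced argmin-DModX assignment.

    The membership limit is a moment-matched scaled chi-square quantile of the
    squared normalized distance (the Nomikos-MacGregor residual limit):
    spectral residuals are strongly correlated across wavelengths, so the
    classical F-quantile with (p - a) nominal degrees of freedom is far too
    tight; matching the first two moments of the calibration distances gives a
    limit with close-to-nominal coverage.  A class whose calibration distances
    are degenerate (zero spread) falls back to the F-quantile.
    """
    if not class_matrices:
        raise ValueError("no classes supplied")
    submodels: dict[str, PcaModel] = {}
    s0: dict[str, float] = {}
    dcrit: dict[str, float] = {}
    for cls, mat in class_matrices.items():
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        n, p = mat.shape
        if n < 3:
            raise ValueError(f"class {cls!r} needs >= 3 calibration samples")
        a = min(n_components, n - 1, p)
        model = fit_pca_nipals(mat, n_components=a, scaling=scaling)
        submodels[cls] = model
        s0[cls] = _dmodx_s0(model, mat)
        e = model.residuals(mat)
        d2 = np.sum(e**2, axis=1) / max(p - a, 1) / max(s0[cls] ** 2, 1e-300)
        m, v = float(np.mean(d2)), float(np.var(d2))
        if v > 1e-12 * max(m, 1.0) ** 2:
            g, h = v / (2 * m), 2 * m**2 / v
            dcrit[cls] = float(np.sqrt(g * stats.chi2.ppf(1.0 - alpha, h)))
        else:
            dof1 = max(p - a, 1)
            dof2 = max((n - a - 1) * (p - a), 1)
            dcrit[cls] = float(np.sqrt(stats.f.ppf(1.0 - alpha, dof1, dof2)))
    return ClassPcaModel(
        submodels=submodels,
        s0=s0,
        dmodx_critical=dcrit,
        alpha=alpha,
        class_order=tuple(class_matrices),
    )


def dmodx(model: ClassPcaModel, x: np.ndarray) -> dict[str, np.ndarray]:
    """Normalized distance to each class model for every row of x."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out: dict[str, np.ndarray] = {}
    for cls, sub in model.submodels.items():
        e = sub.residuals(x)
        p = x.shape[1]
        a = sub.n_components
        s = np.sqrt(np.sum(e**2, axis=1) / max(p - a, 1))
        out[cls] = s / max(model.s0[cls], 1e-300)
    return out


def classify_pca_class(
    model: ClassPcaModel, x: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Forced single-label assignment plus per-class membership flags.

    Returns (labels by argmin normalized DModX, DModX per class, boolean
    membership per class at the alpha threshold).  A sample above every
    threshold is still assigned its nearest class label but carries all-False
    membership flags ("no class").
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 0:
        return (
            np.asarray([], dtype=object),
            {c: np.empty(0) for c in model.class_order},
            {c: np.empty(0, dtype=bool) for c in model.class_order},
        )
    distances = dmodx(model, x)
    stacked = np.vstack([distances[c] for c in model.class_order])
    winner = np.argmin(stacked, axis=0)
    labels = np.asarray([model.class_order[i] for i in winner], dtype=object)
    membership = {c: distances[c] <= model.dmodx_critical[c] for c in model.class_order}
    return labels, distances, membership


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class ModelQuality:
    """Fit/prediction quality of a latent-variable classifier."""

    r2x: float
    r2x_predictive: float
    r2x_orthogonal: float
    r2y: float
    q2y: float | None = None
    rmsee: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


@dataclass
class OplsdaModel:
    """OPLS-DA fit: orthogonal filter + PLS2 predictive block."""

    x_means: np.ndarray
    x_divisors: np.ndarray
    y_means: np.ndarray
    class_order: tuple[str, ...]
    predictive_weights: np.ndarray  # p x a (W)
    predictive_loadings: np.ndarray  # p x a (P)
    predictive_scores: np.ndarray  # n x a (T)
    y_loadings: np.ndarray  # K x a (C)
    orthogonal_weights: np.ndarray  # p x a_o
    orthogonal_loadings: np.ndarray  # p x a_o
    orthogonal_scores: np.ndarray  # n x a_o
    coef: np.ndarray  # p x K regression matrix of the filtered X
    quality: ModelQuality
    scaling: str = "center"

    @property
    def n_predictive(self) -> int:
        return self.predictive_weights.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_weights.shape[1]


@dataclass
class PermutationResult:
    """Label-permutation validation of an OPLS-DA model."""

    correlations: np.ndarray
    r2y_values: np.ndarray
    q2y_values: np.ndarray
    r2y_reference: float
    q2y_reference: float
    r2y_intercept: float
    q2y_intercept: float
    n_permutations: int


def _one_hot(labels, class_order: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        y[i, index[str(lab)]] = 1.0
    return y


def _pls2_component(x: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """One NIPALS PLS2 component: returns (w, t, p, c)."""
    u = y[:, int(np.argmax(np.sum(y**2, axis=0)))].copy()
    w = np.zeros(x.shape[1])
    for _ in range(max_iter):
        w_new = x.T @ u / (u @ u)
        norm = np.linalg.norm(w_new)
        if norm == 0:
            break
        w_new /= norm
        t = x @ w_new
        c = y.T @ t / (t @ t)
        u_new = y @ c / (c @ c)
        if np.linalg.norm(w_new - w) <= tol:
            w = w_new
            break
        w, u = w_new, u_new
    t = x @ w
    p = x.T @ t / (t @ t)
    c = y.T @ t / (t @ t)
    return w, t, p, c


def _fit_opls_core(
    xc: np.ndarray, yc: np.ndarray, n_predictive: int, n_orthogonal: int
) -> dict[str, np.ndarray]:
    """Orthogonal filtering followed by a PLS2 fit on centered data."""
    x = xc.copy()
    n, p = x.shape
    # orthonormal basis of the Y-correlated subspace of X-weight space
    cov = x.T @ yc
    u_basis, sv, _ = np.linalg.svd(cov, full_matrices=False)
    v = u_basis[:, sv > max(sv.max(), 1e-300) * 1e-12] if sv.size else u_basis[:, :0]

    w_orth = np.zeros((p, 0))
    p_orth = np.zeros((p, 0))
    t_orth = np.zeros((n, 0))
    for _ in range(n_orthogonal):
        _, t, p_load, _ = _pls2_component(x, yc)
        wo = p_load - v @ (v.T @ p_load)
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break  # no orthogonal variation left
        wo /= norm
        to = x @ wo
        po = x.T @ to / (to @ to)
        x = x - np.outer(to, po)
        w_orth = np.column_stack([w_orth, wo])
        p_orth = np.column_stack([p_orth, po])
        t_orth = np.column_stack([t_orth, to])

    ws, ts, ps, cs = [], [], [], []
    for _ in range(n_predictive):
        w, t, p_load, c = _pls2_component(x, yc)
        if not np.isfinite(t @ t) or (t @ t) < 1e-300:
            break
        ws.append(w)
        ts.append(t)
        ps.append(p_load)
        cs.append(c)
        x = x - np.outer(t, p_load)
        yc = yc - np.outer(t, c)
    w_mat = np.column_stack(ws) if ws else np.zeros((p, 0))
    t_mat = np.column_stack(ts) if ts else np.zeros((n, 0))
    p_mat = np.column_stack(ps) if ps else np.zeros((p, 0))
    c_mat = np.column_stack(cs) if cs else np.zeros((yc.shape[1], 0))
    if w_mat.shape[1]:
        r = w_mat @ np.linalg.inv(p_mat.T @ w_mat)
        coef = r @ c_mat.T
    else:
        coef = np.zeros((p, yc.shape[1]))
    return {
        "W": w_mat,
        "T": t_mat,
        "P": p_mat,
        "C": c_mat,
        "Wo": w_orth,
        "Po": p_orth,
        "To": t_orth,
        "coef": coef,
    }


def _filter_and_predict(core: dict[str, np.ndarray], xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the training orthogonal filter to centered rows, then predict Yc."""
    x = xc.copy()
    for j in range(core["Wo"].shape[1]):
        to = x @ core["Wo"][:, j]
        x = x - np.outer(to, core["Po"][:, j])
    return x, x @ core["coef"]


def _cv_press(
    x: np.ndarray,
    y: np.ndarray,
    n_predictive: int,
    n_orthogonal: int,
    n_folds: int,
    seed: int,
    scaling: str,
) -> tuple[float, float]:
    """(PRESS, SS) over venetian-blind folds for a fixed component structure."""
    n = x.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError("invalid fold count")
    order = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % n_folds
    press = 0.0
    ss = 0.0
    for fold in range(n_folds):
        test = fold_of == fold
        train = ~test
        xt, x_means, x_div = _scale_matrix(x[train], scaling)
        y_means = y[train].mean(axis=0)
        core = _fit_opls_core(xt, y[train] - y_means, n_predictive, n_orthogonal)
        xc_test = (x[test] - x_means) / x_div
        _, yc_hat = _filter_and_predict(core, xc_test)
        resid = (y[test] - y_means) - yc_hat
        press += float(np.sum(resid**2))
        ss += float(np.sum((y[test] - y_means) ** 2))
    return press, ss


def fit_oplsda(
    x: np.ndarray,
    labels,
    n_predictive: int | None = None,
    max_orthogonal: int = 5,
    cv_folds: int = 7,
    cv_seed: int = 0,
    dq2_threshold: float = 0.01,
    scaling: str = "center",
    n_orthogonal: int | None = None,
) -> OplsdaModel:
    """Fit OPLS-DA on spectra and one-hot class labels.

    The number of predictive components defaults to K - 1.  Orthogonal
    components are added one at a time while the cross-validated Q2Y improves
    by more than ``dq2_threshold``, up to ``max_orthogonal`` (pass
    ``n_orthogonal`` to fix the count instead).  Quality fields cover R2X
    (split into predictive/orthogonal), R2Y, Q2Y, RMSEE, RMSECV and the
    pooled classification triple on the training data.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    labels = np.asarray([str(l) for l in labels], dtype=object)
    class_order = tuple(dict.fromkeys(labels))
    if len(class_order) < 2:
        raise ValueError("need at least two classes")
    if n_predictive is None:
        n_predictive = len(class_order) - 1
    if n_predictive < 1:
        raise ValueError("n_predictive must be >= 1")
    y = _one_hot(labels, class_order)
    n = x.shape[0]

    if n_orthogonal is None:
        best_n_orth = 0
        press, ss = _cv_press(x, y, n_predictive, 0, cv_folds, cv_seed, scaling)
        best_q2 = 1.0 - press / ss
        for n_o in range(1, max_orthogonal + 1):
            press, ss = _cv_press(x, y, n_predictive, n_o, cv_folds, cv_seed, scaling)
            q2 = 1.0 - press / ss
            if q2 > best_q2 + dq2_threshold:
                best_q2, best_n_orth = q2, n_o
            else:
                break
        n_orthogonal = best_n_orth

    xc, x_means, x_div = _scale_matrix(x, scaling)
    y_means = y.mean(axis=0)
    yc = y - y_means
    core = _fit_opls_core(xc, yc, n_predictive, n_orthogonal)

    tss_x = float(np.sum(xc**2))
    r2x_pred = sum(
        float(core["T"][:, a] @ core["T"][:, a]) * float(core["P"][:, a] @ core["P"][:, a])
        for a in range(core["T"].shape[1])
    ) / tss_x
    r2x_orth = sum(
        float(core["To"][:, a] @ core["To"][:, a]) * float(core["Po"][:, a] @ core["Po"][:, a])
        for a in range(core["To"].shape[1])
    ) / tss_x
    _, yc_hat_train = _filter_and_predict(core, xc)
    ss_y = float(np.sum(yc**2))
    r2y = 1.0 - float(np.sum((yc - yc_hat_train) ** 2)) / ss_y

    a_total = core["T"].shape[1] + core["To"].shape[1]
    rmsee = rmse_estimation(yc - yc_hat_train, n_components=a_total, flavor="RMSEE")
    press, ss = _cv_press(x, y, n_predictive, n_orthogonal, cv_folds, cv_seed, scaling)
    q2y = 1.0 - press / ss
    rmsecv = float(np.sqrt(press / (n * y.shape[1])))

    predicted = np.asarray(
        [class_order[i] for i in np.argmax(yc_hat_train + y_means, axis=1)], dtype=object
    )
    cm = confusion_matrix(labels, predicted, class_order)
    _, pooled = ovr_counts(cm)
    accuracy, sensitivity, specificity = core_metrics(pooled)

    quality = ModelQuality(
        r2x=r2x_pred + r2x_orth,
        r2x_predictive=r2x_pred,
        r2x_orthogonal=r2x_orth,
        r2y=r2y,
        q2y=q2y,
        rmsee=rmsee,
        rmsecv=rmsecv,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
    )
    return OplsdaModel(
        x_means=x_means,
        x_divisors=x_div,
        y_means=y_means,
        class_order=class_order,
        predictive_weights=core["W"],
        predictive_loadings=core["P"],
        predictive_scores=core["T"],
        y_loadings=core["C"],
        orthogonal_weights=core["Wo"],
        orthogonal_loadings=core["Po"],
        orthogonal_scores=core["To"],
        coef=core["coef"],
        quality=quality,
        scaling=scaling,
    )


def predict_oplsda(
    model: OplsdaModel, x: np.ndarray, true_labels=None
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Orthogonal-filter new spectra with training weights, then project.

    Returns (labels by argmax predicted dummy, predicted Y, RMSEP or None).
    RMSEP uses divisor N (times the dummy-column count).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.x_means.size:
        raise ValueError("grid mismatch with training data")
    xc = (x - model.x_means) / model.x_divisors
    work = xc.copy()
    for j in range(model.n_orthogonal):
        to = work @ model.orthogonal_weights[:, j]
        work = work - np.outer(to, model.orthogonal_loadings[:, j])
    y_pred = work @ model.coef + model.y_means
    labels = np.asarray([model.class_order[i] for i in np.argmax(y_pred, axis=1)], dtype=object)
    rmsep = None
    if true_labels is not None:
        y_true = _one_hot(np.asarray([str(l) for l in true_labels]), model.class_order)
        rmsep = rmse_estimation(y_true - y_pred, n_components=0, flavor="RMSEP")
    return labels, y_pred, rmsep


def permutation_test(
    x: np.ndarray,
    labels,
    n_permutations: int = 100,
    seed: int = 0,
    n_predictive: int | None = None,
    n_orthogonal: int = 0,
    cv_folds: int = 7,
    scaling: str = "center",
) -> PermutationResult:
    """Label-permutation validation with R2Y / Q2Y intercepts.

    The class labels are permuted uniformly ``n_permutations`` times and the
    model refitted with a fixed component structure each time.  For every fit
    the absolute Pearson correlation between the permuted and the original
    centered dummy matrices is recorded together with R2Y and Q2Y.  A least-
    squares line through the (correlation, metric) points — including the
    unpermuted reference at correlation 1 — is evaluated at correlation 0 to
    give the intercepts.
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    labels = np.asarray([str(l) for l in labels], dtype=object)
    if len(set(labels)) < 2:
        raise ValueError("constant labels cannot be permuted meaningfully")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    class_order = tuple(dict.fromkeys(labels))
    if n_predictive is None:
        n_predictive = len(class_order) - 1
    y_ref = _one_hot(labels, class_order)
    yc_ref = (y_ref - y_ref.mean(axis=0)).ravel()
    denom = float(yc_ref @ yc_ref)

    def _metrics_for(perm_labels: np.ndarray) -> tuple[float, float]:
        y = _one_hot(perm_labels, class_order)
        xc, _, _ = _scale_matrix(x, scaling)
        y_means = y.mean(axis=0)
        core = _fit_opls_core(xc, y - y_means, n_predictive, n_orthogonal)
        _, yc_hat = _filter_and_predict(core, xc)
        yc = y - y_means
        r2y = 1.0 - float(np.sum((yc - yc_hat) ** 2)) / float(np.sum(yc**2))
        press, ss = _cv_press(x, y, n_predictive, n_orthogonal, cv_folds, seed, scaling)
        return r2y, 1.0 - press / ss

    r2y_ref, q2y_ref = _metrics_for(labels)
    rng = np.random.default_rng(seed)
    correlations = np.empty(n_permutations)
    r2y_values = np.empty(n_permutations)
    q2y_values = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_labels = labels[perm]
        y_perm = _one_hot(perm_labels, class_order)
        yc_perm = (y_perm - y_perm.mean(axis=0)).ravel()
        correlations[i] = abs(float(yc_perm @ yc_ref) / denom)
        r2y_values[i], q2y_values[i] = _metrics_for(perm_labels)

    def _intercept(metric: np.ndarray, reference: float) -> float:
        xs = np.concatenate([correlations, [1.0]])
        ys = np.concatenate([metric, [reference]])
        slope, intercept = np.polyfit(xs, ys, 1)
        return float(intercept)

    return PermutationResult(
        correlations=correlations,
        r2y_values=r2y_values,
        q2y_values=q2y_values,
        r2y_reference=r2y_ref,
        q2y_reference=q2y_ref,
        r2y_intercept=_intercept(r2y_values, r2y_ref),
        q2y_intercept=_intercept(q2y_values, q2y_ref),
        n_permutations=n_permutations,
    )


def rmse_estimation(residuals: np.ndarray, n_components: int = 0, flavor: str = "RMSEP") -> float:
    """Root-mean-squared error with the divisor convention of each flavor.

    RMSEE (estimation, on the calibration fit) divides by ``N - 1 - a`` with
    ``a`` the number of fitted components; RMSECV and RMSEP divide by ``N``.
    Multi-column residual matrices additionally divide by the column count so
    the value stays on the scale of a single dummy variable.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim == 1:
        res = res[:, None]
    n, k = res.shape
    total = float(np.sum(res**2))
    flavor = flavor.upper()
    if flavor == "RMSEE":
        dof = n - 1 - n_components
        if dof <= 0:
            raise ValueError("RMSEE undefined: N - 1 - a <= 0")
        return float(np.sqrt(total / (dof * k)))
    if flavor in ("RMSECV", "RMSEP"):
        if n == 0:
            raise ValueError("no residuals")
        return float(np.sqrt(total / (n * k)))
    raise ValueError("flavor must be RMSEE, RMSECV or RMSEP")
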