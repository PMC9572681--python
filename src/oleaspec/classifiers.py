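"""PLS-DA and PCA-DA multi-class classifiers with venetian-blinds cross-validation.

PLS-DA is built from PLS1: one partial least-squares regression (NIPALS) per
class against its {0,1} indicator column; a sample is assigned to the class
with the largest regression response (ties go to the lowest stage).  PCA-DA
performs linear discriminant analysis with equal priors on the first p
un-rotated principal-component scores.  In both, the model dimension (number
of latent variables / components) is the smallest value minimizing the
cross-validated misclassification count under venetian-blinds folds: fold f
holds the samples at positions f, f+n_folds, f+2*n_folds, ... in table order,
so the table's row order defines the folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA

from .spectra import SpectrumTable

__all__ = [
    "ClassifierModel",
    "pls1_nipals",
    "plsda_fit",
    "plsda_predict",
    "pcada_fit",
    "pcada_predict",
    "cv_curve",
    "venetian_folds",
]


def venetian_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Venetian-blinds folds: fold f = row positions f, f+n_folds, f+2*n_folds, ..."""
    if not 1 <= n_folds <= n:
        raise ValueError(f"need 1 <= n_folds <= n, got n_folds={n_folds}, n={n}")
    return [np.arange(f, n, n_folds) for f in range(n_folds)]


def pls1_nipals(
    X: np.ndarray, y: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """PLS1 regression coefficients for every truncation 1..max_components.

    NIPALS on mean-centered data: at each step the weight vector is the
    covariance direction X'y (normalized), scores t = X w, followed by
    deflation of X and y.  For a single response the inner loop converges in
    one pass, so the algorithm is a finite sequence of rank-one deflations.

    Returns
    -------
    B : ndarray, shape (p, max_components)
        Column a-1 holds the regression coefficients using ``a`` components,
        applied to *uncentered* predictors.
    b0 : ndarray, shape (max_components,)
        Matching intercepts.

    If the residual predictor matrix degenerates before ``max_components``
    steps, the remaining columns repeat the last valid solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    k = max_components
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    B = np.zeros((p, k))
    b0 = np.zeros(k)
    tol = max(np.abs(E).max(), 1.0) * 1e-12
    last = None
    for a in range(k):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm <= tol:
            break
        w /= norm
        t = E @ w
        tt = t @ t
        if tt <= tol**2:
            break
        W[:, a] = w
        P[:, a] = E.T @ t / tt
        q[a] = f @ t / tt
        E = E - np.outer(t, P[:, a])
        f = f - q[a] * t
        # coefficients for the first a+1 components
        beta = W[:, : a + 1] @ np.linalg.solve(P[:, : a + 1].T @ W[:, : a + 1], q[: a + 1])
        B[:, a] = beta
        b0[a] = y_mean - x_mean @ beta
        last = a
    if last is None:
        # constant response or zero predictors: intercept-only model
        b0[:] = y_mean
    elif last < k - 1:
        B[:, last + 1 :] = B[:, [last]]
        b0[last + 1 :] = b0[last]
    return B, b0


def _indicator(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def _plsda_train(
    X: np.ndarray, y: np.ndarray, classes: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class PLS1 fits; returns B (p, K, k) and intercepts (K, k)."""
    p = X.shape[1]
    K = len(classes)
    k = min(max_components, max(1, min(X.shape[0] - 1, p)))
    B = np.zeros((p, K, max_components))
    b0 = np.zeros((K, max_components))
    Y = _indicator(y, classes)
    for c in range(K):
        Bc, b0c = pls1_nipals(X, Y[:, c], k)
        B[:, c, :k], b0[c, :k] = Bc, b0c
        if k < max_components:
            B[:, c, k:] = Bc[:, [k - 1]]
            b0[c, k:] = b0c[k - 1]
    return B, b0


def _plsda_responses(X: np.ndarray, B: np.ndarray, b0: np.ndarray, k: int) -> np.ndarray:
    return X @ B[:, :, k - 1] + b0[:, k - 1]


def _assign(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # argmax returns the first maximum, so ties resolve to the lowest stage
    return classes[np.argmax(scores, axis=1)]


@dataclass
class ClassifierModel:
    """Fitted PLS-DA or PCA-DA state.

    For PLS-DA: ``coef``/``intercept`` are the per-class regression
    coefficients at the chosen latent dimension.  For PCA-DA: ``pca_center``
    and ``pca_loadings`` map spectra to scores and ``coef``/``intercept`` are
    the discriminant functions on the first ``n_components`` scores.
    """

    method: str
    classes: np.ndarray
    n_components: int
    coef: np.ndarray
    intercept: np.ndarray
    wavelengths: np.ndarray
    preprocessing: str = "none"
    pca_center: np.ndarray | None = None
    pca_loadings: np.ndarray | None = None
    cv_errors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.method == "plsda":
            return plsda_predict(self, X)[0]
        return pcada_predict(self, X)

    def save(self, path) -> None:
        np.savez(
            path,
            method=self.method,
            classes=self.classes,
            n_components=self.n_components,
            coef=self.coef,
            intercept=self.intercept,
            wavelengths=self.wavelengths,
            preprocessing=self.preprocessing,
            pca_center=self.pca_center if self.pca_center is not None else np.array([]),
            pca_loadings=self.pca_loadings if self.pca_loadings is not None else np.array([]),
            cv_errors=self.cv_errors if self.cv_errors is not None else np.array([]),
        )

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        z = np.load(path, allow_pickle=False)
        return cls(
            method=str(z["method"]),
            classes=z["classes"],
            n_components=int(z["n_components"]),
            coef=z["coef"],
            intercept=z["intercept"],
            wavelengths=z["wavelengths"],
            preprocessing=str(z["preprocessing"]),
            pca_center=z["pca_center"] if z["pca_center"].size else None,
            pca_loadings=z["pca_loadings"] if z["pca_loadings"].size else None,
            cv_errors=z["cv_errors"] if z["cv_errors"].size else None,
        )


def _check_fit_inputs(X: np.ndarray, y: np.ndarray, cv_folds: int) -> np.ndarray:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    if X.shape[0] < cv_folds:
        raise ValueError(f"cv_folds={cv_folds} exceeds sample count {X.shape[0]}")
    return classes


def _cv_misclass_plsda(
    X: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    max_components: int,
    cv_folds: int,
    criterion: str = "misclassification",
) -> np.ndarray:
    """Per-dimension venetian-blinds CV error curve (misclassification count or PRESS)."""
    n = X.shape[0]
    errors = np.zeros(max_components)
    for fold in venetian_folds(n, cv_folds):
        train = np.setdiff1d(np.arange(n), fold)  # sorted: preserves table order
        B, b0 = _plsda_train(X[train], y[train], classes, max_components)
        Y_val = _indicator(y[fold], classes)
        for k in range(1, max_components + 1):
            scores = _plsda_responses(X[fold], B, b0, k)
            if criterion == "press":
                errors[k - 1] += np.sum((Y_val - scores) ** 2)
            else:
                errors[k - 1] += np.sum(_assign(scores, classes) != y[fold])
    return errors


def plsda_fit(
    table: SpectrumTable,
    max_lv: int = 20,
    cv_folds: int = 10,
    criterion: str = "misclassification",
) -> ClassifierModel:
    """Fit PLS-DA on the table's calibration rows.

    One PLS1 model per class against its {0,1} indicator; the latent
    dimension is the smallest value of 1..max_lv minimizing the
    venetian-blinds cross-validated misclassification count (``criterion=
    "press"`` switches to the prediction error sum of squares on the
    indicator responses).
    """
    cal = table.calibration()
    classes = _check_fit_inputs(cal.X, cal.y, cv_folds)
    max_lv = min(max_lv, cal.n_bands, cal.n_samples - 1)
    errors = _cv_misclass_plsda(cal.X, cal.y, classes, max_lv, cv_folds, criterion)
    n_components = int(np.argmin(errors)) + 1
    B, b0 = _plsda_train(cal.X, cal.y, classes, n_components)
    return ClassifierModel(
        method="plsda",
        classes=classes,
        n_components=n_components,
        coef=B[:, :, n_components - 1],
        intercept=b0[:, n_components - 1],
        wavelengths=cal.wavelengths.copy(),
        preprocessing=str(table.meta.get("preprocessing", "none")),
        cv_errors=errors,
        meta={"cv_folds": cv_folds, "criterion": criterion},
    )


def plsda_predict(model: ClassifierModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stage labels plus the per-class regression responses.

    Assignment is argmax over the class responses; exact ties resolve to the
    lowest stage index.  Prediction is stateless: each row is scored
    independently of the others.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"X has {X.shape[1]} bands, model expects {model.n_bands} "
            f"(preprocessing tag: {model.preprocessing!r})"
        )
    scores = X @ model.coef + model.intercept
    return _assign(scores, model.classes), scores


def _lda_equal_priors(scores: np.ndarray, y: np.ndarray, classes: np.ndarray):
    lda = LinearDiscriminantAnalysis(priors=np.full(len(classes), 1.0 / len(classes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear scores are handled by the svd solver
        lda.fit(scores, y)
    return lda


def _cv_misclass_pcada(
    X: np.ndarray, y: np.ndarray, classes: np.ndarray, max_components: int, cv_folds: int
) -> np.ndarray:
    n = X.shape[0]
    errors = np.zeros(max_components)
    for fold in venetian_folds(n, cv_folds):
        train = np.setdiff1d(np.arange(n), fold)
        kmax = min(max_components, len(train) - 1, X.shape[1])
        pca = PCA(n_components=kmax, svd_solver="full").fit(X[train])
        s_train = pca.transform(X[train])
        s_val = pca.transform(X[fold])
        for p in range(1, max_components + 1):
            pp = min(p, kmax)
            lda = _lda_equal_priors(s_train[:, :pp], y[train], classes)
            errors[p - 1] += np.sum(lda.predict(s_val[:, :pp]) != y[fold])
    return errors


def pcada_fit(table: SpectrumTable, max_pc: int = 20, cv_folds: int = 10) -> ClassifierModel:
    """Fit PCA-DA on the calibration rows: LDA with equal priors on un-rotated PC scores.

    The number of retained PCs is chosen by the same venetian-blinds CV
    criterion as PLS-DA.  If the within-class covariance is singular at the
    requested dimension, the dimension is reduced with a warning.
    """
    cal = table.calibration()
    classes = _check_fit_inputs(cal.X, cal.y, cv_folds)
    max_pc = min(max_pc, cal.n_bands, cal.n_samples - 1)
    errors = _cv_misclass_pcada(cal.X, cal.y, classes, max_pc, cv_folds)
    n_components = int(np.argmin(errors)) + 1
    counts = np.bincount(np.searchsorted(classes, cal.y))
    max_safe = cal.n_samples - len(classes)
    if n_components > max_safe and max_safe >= 1:
        warnings.warn(
            f"pooled within-class covariance singular at p={n_components}; reducing to {max_safe}"
        )
        n_components = max_safe
    if counts.min() < 2:
        raise ValueError("each class needs at least two calibration samples for PCA-DA")
    pca = PCA(n_components=n_components, svd_solver="full").fit(cal.X)
    lda = _lda_equal_priors(pca.transform(cal.X), cal.y, classes)
    coef = lda.coef_ if lda.coef_.ndim == 2 else lda.coef_[None, :]
    return ClassifierModel(
        method="pcada",
        classes=classes,
        n_components=n_components,
        coef=np.asarray(coef),
        intercept=np.asarray(lda.intercept_).ravel(),
        wavelengths=cal.wavelengths.copy(),
        preprocessing=str(table.meta.get("preprocessing", "none")),
        pca_center=pca.mean_.copy(),
        pca_loadings=pca.components_.T.copy(),
        cv_errors=errors,
        meta={"cv_folds": cv_folds},
    )


def pcada_predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Stage labels from the discriminant functions on the PC scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(f"X has {X.shape[1]} bands, model expects {model.n_bands}")
    scores = (X - model.pca_center) @ model.pca_loadings
    decision = scores @ model.coef.T + model.intercept
    if len(model.classes) == 2:
        # binary LDA exposes a single discriminant; positive favors classes[1]
        labels = np.where(decision.ravel() > 0, model.classes[1], model.classes[0])
        return labels
    return _assign(decision, model.classes)


def cv_curve(
    table: SpectrumTable,
    method: str = "plsda",
    max_components: int = 20,
    cv_folds: int = 10,
    criterion: str = "misclassification",
) -> np.ndarray:
    """Per-dimension venetian-blinds CV misclassification counts on the calibration rows.

    Deterministic given table row order; the fitted model's ``n_components``
    is the position of the curve's first minimum.
    """
    cal = table.calibration()
    classes = _check_fit_inputs(cal.X, cal.y, cv_folds)
    max_components = min(max_components, cal.n_bands, cal.n_samples - 1)
    if method == "plsda":
        return _cv_misclass_plsda(cal.X, cal.y, classes, max_components, cv_folds, criterion)
    if method == "pcada":
        return _cv_misclass_pcada(cal.X, cal.y, classes, max_components, cv_folds)
    raise ValueError(f"unknown method {method!r}")
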