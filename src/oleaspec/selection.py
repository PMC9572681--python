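"""Key-wavelength selection: UVE, SPA (chained as UVE+SPA), and synchronous 2D-COS.

UVE (uninformative variable elimination) appends artificial noise variables
to the spectra, fits leave-one-out PLS1 submodels per class, and discards
every real band whose regression-coefficient stability (mean/sd across
submodels) does not exceed that of the noise block.

SPA (successive projections algorithm) greedily grows band chains that
maximize the projection norm orthogonal to the span of already-chosen bands
(minimal collinearity), then keeps the chain prefix with the lowest
cross-validated RMSE of a PLS-DA model restricted to those bands.

Synchronous 2D-COS treats maturity stage as the external perturbation: the
synchronous spectrum is the covariance matrix of the stage-mean spectra after
subtracting the perturbation-mean reference, and its diagonal autopeaks mark
maturity-sensitive bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .classifiers import pls1_nipals, venetian_folds
from .selection_result import SelectionResult
from .spectra import SpectrumTable

__all__ = [
    "SelectionResult",
    "SynchronousSpectrum",
    "uve_select",
    "spa_select",
    "spa_chain",
    "uve_spa",
    "stage_mean_spectra",
    "synchronous_2dcos",
    "autopeaks",
]


def _class_indicators(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("selection requires at least two classes (constant indicator)")
    return classes, (y[:, None] == classes[None, :]).astype(float)


def uve_select(
    table: SpectrumTable,
    n_noise: int | None = None,
    n_lv: int | None = None,
    cutoff_rule: str | float = "max",
    noise_scale: float = 1e-10,
    seed: int = 0,
) -> SelectionResult:
    """Uninformative variable elimination on the calibration rows.

    ``n_noise`` uniform-random columns scaled by ``noise_scale`` (numerically
    negligible) are appended to X — by default as many as there are real
    bands.  Leave-one-out PLS1 submodels are fitted against each class
    indicator, concatenating the per-class coefficient vectors, so each
    (variable, class) pair gets a stability s = mean(b)/sd(b) across the n
    submodels.  The cutoff is symmetric about zero at the maximum |s| over
    the noise block (``cutoff_rule="max"``) or at a percentile of it (pass a
    float, e.g. 99); a real band is retained when its stability exceeds the
    cutoff for at least one class indicator.

    ``n_lv`` defaults to the venetian-blinds CV-optimal latent dimension of
    a full-spectrum PLS-DA on the same calibration rows: submodel
    coefficients at the working model dimension are what the stability
    analysis is about, and over-dimensioned submodels fit noise, flattening
    the real/noise stability contrast.
    """
    cal = table.calibration()
    n, p = cal.X.shape
    if n < 3:
        raise ValueError("UVE needs at least 3 calibration samples")
    classes, Y = _class_indicators(cal.y)
    if n_noise is None:
        n_noise = p
    if n_lv is None:
        from .classifiers import cv_curve

        curve = cv_curve(cal, "plsda", max_components=min(15, n - 2, p),
                         cv_folds=min(10, n))
        n_lv = int(np.argmin(curve)) + 1
    n_lv = min(n_lv, n - 2, p)
    rng = np.random.default_rng(seed)
    noise = rng.uniform(size=(n, n_noise)) * noise_scale
    X_aug = np.hstack([cal.X, noise])
    rows = np.arange(n)
    K = len(classes)
    coefs = np.empty((n, K, p + n_noise))  # submodel x class x variable
    for i in range(n):
        keep = rows != i
        for c in range(K):
            B, _ = pls1_nipals(X_aug[keep], Y[keep, c], n_lv)
            coefs[i, c] = B[:, n_lv - 1]
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(sd > 0, coefs.mean(axis=0) / np.where(sd > 0, sd, 1.0), 0.0)
    noise_abs = np.abs(stability[:, p:])
    if cutoff_rule == "max":
        cutoff = float(noise_abs.max()) if n_noise else 0.0
    else:
        cutoff = float(np.percentile(noise_abs, float(cutoff_rule)))
    best = np.abs(stability[:, :p]).max(axis=0)
    retained = np.flatnonzero(best > cutoff)
    return SelectionResult(
        method="uve",
        selected=retained,
        wavelengths=cal.wavelengths[retained] if retained.size else np.array([]),
        diagnostics={
            "stability": stability,
            "cutoff": cutoff,
            "n_noise": n_noise,
            "n_lv": n_lv,
        },
    )


def spa_chain(
    X: np.ndarray, candidates: np.ndarray, start: int, k_max: int
) -> list[int]:
    """One SPA chain: successive orthogonal projections from a starting band.

    ``X`` holds calibration spectra (columns mean-centered internally);
    ``start`` indexes into ``candidates``.  At each step the remaining
    candidate with the largest residual norm orthogonal to the span of the
    chosen columns is added (exact ties resolve to the lowest band index).
    The chain truncates with a warning if the span becomes rank deficient.
    """
    candidates = np.asarray(candidates, dtype=int)
    V = X[:, candidates] - X[:, candidates].mean(axis=0)
    V = V.astype(float).copy()
    m = len(candidates)
    tol = 1e-10 * max(float(np.linalg.norm(V, axis=0).max()), 1.0)
    chain = [start]
    available = np.ones(m, dtype=bool)
    available[start] = False
    current = start
    for _ in range(k_max - 1):
        q = V[:, current]
        norm_q = np.linalg.norm(q)
        if norm_q <= tol:
            warnings.warn("SPA span became rank deficient; chain truncated")
            break
        q = q / norm_q
        V = V - np.outer(q, q @ V)  # project all columns off the chosen direction
        norms = np.linalg.norm(V, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol:
            warnings.warn("SPA span became rank deficient; chain truncated")
            break
        chain.append(nxt)
        available[nxt] = False
        current = nxt
    return chain


def _plsda_cv_rmse(
    X: np.ndarray, Y: np.ndarray, n_components: int, cv_folds: int
) -> float:
    """Venetian-blinds CV RMSE of per-class PLS1 predictions of the indicator matrix."""
    n = X.shape[0]
    sq_err = 0.0
    count = 0
    for fold in venetian_folds(n, cv_folds):
        train = np.setdiff1d(np.arange(n), fold)
        k = min(n_components, len(train) - 1, X.shape[1])
        for c in range(Y.shape[1]):
            B, b0 = pls1_nipals(X[train], Y[train, c], k)
            pred = X[fold] @ B[:, k - 1] + b0[k - 1]
            sq_err += float(np.sum((Y[fold, c] - pred) ** 2))
            count += len(fold)
    return float(np.sqrt(sq_err / count))


def spa_select(
    table: SpectrumTable,
    candidates: np.ndarray | None = None,
    k_max: int = 15,
    cv_folds: int = 10,
    max_lv: int = 10,
) -> SelectionResult:
    """Successive projections algorithm over a candidate band set.

    Chains are grown from every candidate as a starting band; for each chain
    prefix of length k the venetian-blinds CV RMSE of a PLS-DA model on those
    k bands (latent dimension min(k, ``max_lv``)) is evaluated, and the
    (start, k) pair with the global RMSE minimum wins — ties go to the
    smaller k, then the earlier start.  Results are invariant to permuting
    the candidate order: candidates are sorted internally and exact
    projection-norm ties resolve to the lowest band index.
    """
    cal = table.calibration()
    if candidates is None:
        candidates = np.arange(cal.n_bands)
    candidates = np.unique(np.asarray(candidates, dtype=int))
    if candidates.size == 0:
        raise ValueError("SPA candidate set is empty")
    if not (1 <= k_max <= candidates.size):
        raise ValueError(f"k_max must be in 1..{candidates.size}")
    _, Y = _class_indicators(cal.y)
    cache: dict[tuple[int, ...], float] = {}
    best = None  # (rmse, k, start, chain)
    best_curve = None
    for start in range(candidates.size):
        chain = spa_chain(cal.X, candidates, start, k_max)
        curve = []
        for k in range(1, len(chain) + 1):
            bands = tuple(sorted(candidates[chain[:k]]))
            if bands not in cache:
                cache[bands] = _plsda_cv_rmse(
                    cal.X[:, list(bands)], Y, min(k, max_lv), cv_folds
                )
            curve.append(cache[bands])
            key = (cache[bands], k, start)
            if best is None or key < best[:3]:
                best = (cache[bands], k, start, chain[:k])
                best_curve = list(curve)
    rmse, k_best, start_best, chain_best = best
    selected = np.sort(candidates[chain_best])
    return SelectionResult(
        method="spa",
        selected=selected,
        wavelengths=cal.wavelengths[selected],
        diagnostics={
            "rmse": rmse,
            "rmse_curve": best_curve,
            "selection_order": candidates[chain_best].tolist(),
            "start_band": int(candidates[start_best]),
            "k": k_best,
        },
    )


def uve_spa(
    table: SpectrumTable,
    k_max: int = 15,
    cv_folds: int = 10,
    uve_kwargs: dict | None = None,
    spa_kwargs: dict | None = None,
) -> SelectionResult:
    """UVE first, then SPA restricted to the UVE-retained bands.

    The final selection is always a subset of the UVE-retained set; fewer
    than two retained bands is an error suggesting a relaxed cutoff.
    """
    uve = uve_select(table, **(uve_kwargs or {}))
    if uve.n_selected < 2:
        raise ValueError(
            f"UVE retained only {uve.n_selected} band(s); relax the cutoff "
            "(e.g. cutoff_rule=99) before chaining SPA"
        )
    spa = spa_select(
        table,
        candidates=uve.selected,
        k_max=min(k_max, uve.n_selected),
        cv_folds=cv_folds,
        **(spa_kwargs or {}),
    )
    diagnostics = {"uve": uve.diagnostics, "spa": spa.diagnostics,
                   "n_uve_retained": uve.n_selected}
    return SelectionResult(
        method="uve_spa",
        selected=spa.selected,
        wavelengths=spa.wavelengths,
        diagnostics=diagnostics,
    )


@dataclass
class SynchronousSpectrum:
    """Synchronous 2D correlation spectrum over an ordered perturbation series.

    ``matrix`` is the bands x bands covariance of the dynamic spectra
    (perturbation-mean subtracted); symmetric positive semidefinite with a
    non-negative diagonal equal to the per-band variance.
    """

    matrix: np.ndarray
    wavelengths: np.ndarray
    perturbation: str = "maturity stages S1..S5"

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def stage_mean_spectra(table: SpectrumTable) -> np.ndarray:
    """Class-mean spectra of the calibration rows, ordered by ascending stage."""
    cal = table.calibration()
    return np.vstack([cal.X[cal.y == s].mean(axis=0) for s in np.unique(cal.y)])


def synchronous_2dcos(
    spectra: np.ndarray, wavelengths: np.ndarray | None = None
) -> SynchronousSpectrum:
    """Synchronous 2D-COS matrix of an m x bands perturbation-ordered series.

    Dynamic spectra are the rows minus their perturbation mean (the Noda
    reference convention); the synchronous spectrum is ``Ydyn.T @ Ydyn /
    (m - 1)``.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need at least 2 perturbation points (rows)")
    m = spectra.shape[0]
    dyn = spectra - spectra.mean(axis=0)
    matrix = dyn.T @ dyn / (m - 1)
    if wavelengths is None:
        wavelengths = np.arange(spectra.shape[1], dtype=float)
    return SynchronousSpectrum(matrix=matrix, wavelengths=np.asarray(wavelengths, float))


def autopeaks(
    sync: SynchronousSpectrum, min_prominence: float | None = None
) -> SelectionResult:
    """Local maxima of the synchronous diagonal passing a prominence filter.

    The default prominence is 10% of the diagonal's range; a monotone
    diagonal yields an empty selection.
    """
    diag = sync.diagonal
    span = float(diag.max() - diag.min()) if diag.size else 0.0
    prom = min_prominence if min_prominence is not None else 0.1 * span
    if span == 0.0:
        indices = np.array([], dtype=int)
    else:
        indices, _ = find_peaks(diag, prominence=prom)
    return SelectionResult(
        method="2dcos",
        selected=indices,
        wavelengths=sync.wavelengths[indices] if indices.size else np.array([]),
        diagnostics={"diagonal": diag, "prominence": prom},
    )
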