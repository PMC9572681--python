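"""Exploratory PCA: scores, explained variance, score images, loading-line peak picking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .cube_io import Hypercube
from .segmentation import Mask
from .spectra import SpectrumTable
from .selection_result import SelectionResult

__all__ = ["PcaModel", "pca_fit", "pca_scores", "score_image", "loading_peaks"]


@dataclass
class PcaModel:
    """Mean-centered PCA of a spectra matrix.

    ``loadings`` is bands x k with orthonormal columns, sign-canonicalized so
    the largest-magnitude element of each loading is positive (PCA is only
    defined up to per-component sign; the convention makes results
    reproducible).  ``explained_pct`` is the percentage of total variance per
    component, non-increasing.
    """

    loadings: np.ndarray
    explained_pct: np.ndarray
    center: np.ndarray
    wavelengths: np.ndarray
    k: int


def pca_fit(table: SpectrumTable, k: int) -> PcaModel:
    """Fit a k-component mean-centered PCA to a table's spectra."""
    n, p = table.X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for {n} samples x {p} bands")
    model = PCA(n_components=k, svd_solver="full").fit(table.X)
    loadings = model.components_.T.copy()  # bands x k
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
    return PcaModel(
        loadings=loadings,
        explained_pct=model.explained_variance_ratio_ * 100.0,
        center=model.mean_.copy(),
        wavelengths=table.wavelengths.copy(),
        k=k,
    )


def pca_scores(model: PcaModel, X: np.ndarray) -> np.ndarray:
    """Project spectra into the PC space: ``(X - center) @ loadings``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError("X band count does not match the fitted model")
    return (X - model.center) @ model.loadings


def score_image(
    model: PcaModel,
    cube: Hypercube,
    mask: Mask,
    pc_index: int,
    sentinel: float = np.nan,
) -> np.ndarray:
    """Per-pixel projection of a cube onto one loading; background is ``sentinel``.

    ``pc_index`` counts from 1 (PC1 is the first component).
    """
    if not 1 <= pc_index <= model.k:
        raise ValueError(f"pc_index {pc_index} out of range 1..{model.k}")
    if cube.n_bands != model.loadings.shape[0]:
        raise ValueError("cube band count does not match the fitted model")
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    image = np.full(cube.shape[:2], sentinel, dtype=float)
    fg = mask.values
    if fg.any():
        image[fg] = (cube.data[fg] - model.center) @ model.loadings[:, pc_index - 1]
    return image


def loading_peaks(
    model: PcaModel,
    n_pcs: int = 3,
    min_prominence: float | None = None,
) -> SelectionResult:
    """Wavelengths at pronounced peaks and valleys of the first ``n_pcs`` loading lines.

    Extrema of each loading line (maxima of the line and of its negation) are
    kept when their prominence exceeds ``min_prominence``; the default is 10%
    of that loading line's range.  Wavelengths picked by several components
    are merged once; the result is sorted and lies inside the grid.
    """
    if n_pcs > model.k:
        raise ValueError(f"n_pcs={n_pcs} exceeds fitted components k={model.k}")
    picked: set[int] = set()
    for j in range(n_pcs):
        line = model.loadings[:, j]
        span = float(line.max() - line.min())
        if span == 0.0:
            continue
        prom = min_prominence if min_prominence is not None else 0.1 * span
        for signed in (line, -line):
            idx, _ = find_peaks(signed, prominence=prom)
            picked.update(int(i) for i in idx)
    indices = np.array(sorted(picked), dtype=int)
    return SelectionResult(
        method="pc_loadings",
        selected=indices,
        wavelengths=model.wavelengths[indices] if indices.size else np.array([]),
        diagnostics={"n_pcs": n_pcs, "explained_pct": model.explained_pct[:n_pcs].tolist()},
    )
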