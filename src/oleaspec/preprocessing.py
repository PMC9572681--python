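"""Band trimming and per-spectrum pre-treatments: SNV, max-min normalization, SG derivatives.

All treatments operate row-wise (one spectrum at a time) and therefore use no
cross-sample statistics — preprocessing a table can never leak information
between the calibration and prediction splits.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectrumTable

__all__ = [
    "trim_bands",
    "snv",
    "minmax_normalize",
    "sg_derivative",
    "preprocess",
    "PREPROCESSORS",
]


def trim_bands(table: SpectrumTable, lo: float = 400.0, hi: float = 1000.0) -> SpectrumTable:
    """Keep bands with ``lo <= wavelength <= hi`` (default 400-1000 nm).

    Sensor edges are noisy; the conventional VNIR working range drops them.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    keep = (table.wavelengths >= lo) & (table.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands remain in [{lo}, {hi}] nm")
    return table.with_X(table.X[:, keep], table.wavelengths[keep])


def _check_rows_vary(X: np.ndarray, what: str) -> None:
    flat = np.flatnonzero(X.std(axis=1) == 0)
    if flat.size:
        raise ValueError(f"{what} undefined for constant spectra (rows {flat.tolist()})")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: center each spectrum and scale to unit sd (ddof=1)."""
    X = np.asarray(X, dtype=float)
    _check_rows_vary(X, "SNV")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    return (X - mu) / sd


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Max-min normalization: map each spectrum onto [0, 1] exactly."""
    X = np.asarray(X, dtype=float)
    _check_rows_vary(X, "max-min normalization")
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    return (X - lo) / (hi - lo)


def sg_derivative(X: np.ndarray, order: int, window: int = 7, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative along the band axis.

    A degree-``polyorder`` polynomial is least-squares fitted in each sliding
    window of ``window`` points and its ``order``-th derivative evaluated at
    the window center; at the edges the edge-window polynomial itself is
    evaluated, so no bands are lost.  The derivative is per band-index step
    (unit spacing), not per nm.
    """
    X = np.asarray(X, dtype=float)
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if X.shape[-1] < window:
        raise ValueError(f"need at least {window} bands, got {X.shape[-1]}")
    if order > polyorder:
        raise ValueError("derivative order cannot exceed polyorder")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         deriv=order, delta=1.0, axis=-1, mode="interp")


#: preprocessing registry keyed by the config enum {none, snv, normalization, d1, d2}
PREPROCESSORS = {
    "none": lambda X: np.asarray(X, dtype=float),
    "snv": snv,
    "normalization": minmax_normalize,
    "d1": lambda X: sg_derivative(X, order=1),
    "d2": lambda X: sg_derivative(X, order=2),
}


def preprocess(table: SpectrumTable, method: str) -> SpectrumTable:
    """Apply a named pre-treatment to every spectrum of a table."""
    if method not in PREPROCESSORS:
        raise ValueError(f"unknown preprocessing {method!r}; options: {sorted(PREPROCESSORS)}")
    out = table.with_X(PREPROCESSORS[method](table.X))
    out.meta = dict(table.meta, preprocessing=method)
    return out
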