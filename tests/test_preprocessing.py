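"""Spectral pre-treatment contracts: trimming, SNV, max-min, SG derivatives."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oleaspec import SpectrumTable, minmax_normalize, sg_derivative, snv, trim_bands
from oleaspec import simulate_spectra

row_strategy = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=8, max_size=20
).filter(lambda r: np.std(r) > 1e-6)


def _table(wl, X=None, y=None):
    X = np.zeros((2, len(wl))) if X is None else X
    y = np.array([1, 2])[: X.shape[0]] if y is None else y
    return SpectrumTable(X, np.asarray(wl, float), y)


class TestTrim:
    def test_grid_inside_range_is_identity(self):
        t = _table(np.linspace(400, 1000, 119))
        assert trim_bands(t).n_bands == 119

    def test_sensor_grid_trims_to_working_range(self):
        # full sensor span at 2.8 nm resolution trims to the 400-1000 nm window
        wl = np.arange(336.2, 1092.5, 2.8)
        trimmed = trim_bands(_table(wl))
        assert trimmed.wavelengths.min() >= 400.0
        assert trimmed.wavelengths.max() <= 1000.0
        assert trimmed.n_bands < len(wl)

    def test_degenerate_range_raises(self):
        t = _table(np.linspace(400, 1000, 10))
        with pytest.raises(ValueError):
            trim_bands(t, 500.0, 500.1)


class TestSnv:
    def test_closed_form(self):
        assert np.allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]])

    def test_rows_have_zero_mean_unit_sd(self, rng):
        out = snv(rng.normal(2.0, 3.0, size=(5, 30)))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(row=row_strategy, a=st.floats(0.01, 50), b=st.floats(-50, 50))
    def test_affine_invariance(self, row, a, b):
        x = np.array([row])
        assert np.allclose(snv(a * x + b), snv(x), atol=1e-6)

    def test_constant_row_names_the_sample(self):
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            snv(np.array([[1.0, 2.0], [3.0, 3.0]]))


class TestMinMax:
    def test_closed_form(self):
        assert np.allclose(minmax_normalize(np.array([[2.0, 4.0, 6.0]])), [[0.0, 0.5, 1.0]])

    def test_range_is_exactly_unit(self, rng):
        out = minmax_normalize(rng.normal(size=(4, 25)))
        assert np.allclose(out.min(axis=1), 0.0)
        assert np.allclose(out.max(axis=1), 1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(row=row_strategy, a=st.floats(0.01, 50), b=st.floats(-50, 50))
    def test_affine_invariance(self, row, a, b):
        x = np.array([row])
        assert np.allclose(minmax_normalize(a * x + b), minmax_normalize(x), atol=1e-6)


def _sg_oracle(X, order, window=7, polyorder=2):
    """Direct windowed least-squares polynomial fit, evaluated per point.

    Interior points use the centered window; edge points evaluate the
    polynomial fitted on the first/last window at their own position.
    """
    X = np.atleast_2d(X)
    n = X.shape[1]
    hw = window // 2
    out = np.empty_like(X, dtype=float)
    fact = {1: 1.0, 2: 2.0}[order]
    for r in range(X.shape[0]):
        for i in range(n):
            lo = min(max(i - hw, 0), n - window)
            t = np.arange(lo, lo + window)
            coeffs = np.polyfit(t, X[r, lo : lo + window], polyorder)
            deriv = np.polyder(np.poly1d(coeffs), order)
            out[r, i] = deriv(i)
    return out


class TestSgDerivative:
    def test_quadratic_second_derivative_is_constant_two(self):
        x = np.arange(15.0) ** 2
        assert np.allclose(sg_derivative(x[None, :], order=2), 2.0)

    def test_line_first_derivative_constant_second_zero(self):
        x = 3.0 * np.arange(20.0) + 7.0
        assert np.allclose(sg_derivative(x[None, :], order=1), 3.0)
        assert np.allclose(sg_derivative(x[None, :], order=2), 0.0, atol=1e-10)

    def test_matches_windowed_polyfit_oracle(self, rng):
        X = rng.normal(size=(3, 16))
        for order in (1, 2):
            assert np.allclose(sg_derivative(X, order), _sg_oracle(X, order), atol=1e-8)

    def test_linearity(self, rng):
        x, z = rng.normal(size=(1, 30)), rng.normal(size=(1, 30))
        lhs = sg_derivative(2.5 * x - 1.5 * z, order=2)
        rhs = 2.5 * sg_derivative(x, order=2) - 1.5 * sg_derivative(z, order=2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize(
        "kwargs", [{"window": 6}, {"window": 1}, {"order": 3}, {"window": 7, "polyorder": 7}]
    )
    def test_precondition_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            sg_derivative(np.zeros((1, 30)), order=kwargs.pop("order", 2), **kwargs)

    def test_too_few_bands_raise(self):
        with pytest.raises(ValueError, match="bands"):
            sg_derivative(np.zeros((1, 5)), order=1)


def test_snv_reduces_within_class_variance_share_on_scatter_corrupted_data():
    """Per-sample gain/offset jitter inflates within-class variance; SNV removes it."""
    table = simulate_spectra(8, seed=9, gain_jitter_sd=0.08, offset_jitter_sd=0.01)

    def within_share(X):
        total = X.var(axis=0).sum()
        within = np.mean(
            [X[table.y == s].var(axis=0).sum() for s in np.unique(table.y)]
        )
        return within / total

    assert within_share(snv(table.X)) < within_share(table.X)
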