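"""Wavelength selection: UVE stability, SPA projections, synchronous 2D-COS."""

from __future__ import annotations

import numpy as np
import pytest

from oleaspec import (
    SpectrumTable,
    autopeaks,
    spa_select,
    synchronous_2dcos,
    uve_select,
    uve_spa,
)
from oleaspec.selection import spa_chain, stage_mean_spectra


class TestUve:
    def _informative_fixture(self, n=30, n_noise_bands=50, seed=4):
        """Band 0 is the class indicator itself; the rest is pure noise."""
        rng = np.random.default_rng(seed)
        y = np.repeat([1, 2], n // 2)
        X = rng.normal(size=(n, 1 + n_noise_bands))
        X[:, 0] = (y == 2).astype(float)
        order = rng.permutation(n)
        wl = np.linspace(400, 1000, 1 + n_noise_bands)
        return SpectrumTable(X[order], wl, y[order])

    def test_informative_band_kept_noise_bands_dropped(self):
        table = self._informative_fixture()
        result = uve_select(table, seed=0)
        assert 0 in result.selected
        noise_survivors = np.sum(result.selected > 0)
        assert noise_survivors <= 0.1 * 50

    def test_pure_noise_retains_almost_nothing(self):
        rng = np.random.default_rng(8)
        y = np.repeat([1, 2, 3, 4, 5], 8)
        X = rng.normal(size=(40, 60))
        table = SpectrumTable(X, np.linspace(400, 1000, 60), y)
        result = uve_select(table, n_lv=3, seed=0)
        assert result.n_selected <= 0.05 * 60

    def test_noise_block_defaults_to_band_count(self):
        table = self._informative_fixture()
        result = uve_select(table, seed=0)
        assert result.diagnostics["n_noise"] == table.n_bands

    def test_stability_invariant_to_positive_rescaling(self):
        table = self._informative_fixture()
        a = uve_select(table, n_lv=2, seed=0)
        scaled = SpectrumTable(3.7 * table.X, table.wavelengths, table.y)
        b = uve_select(scaled, n_lv=2, seed=0)
        p = table.n_bands
        assert np.allclose(
            a.diagnostics["stability"][:, :p], b.diagnostics["stability"][:, :p], rtol=1e-6
        )
        assert np.array_equal(a.selected, b.selected)

    def test_single_class_raises(self):
        rng = np.random.default_rng(0)
        table = SpectrumTable(rng.normal(size=(10, 5)), np.arange(5.0), np.ones(10, int))
        with pytest.raises(ValueError, match="two classes"):
            uve_select(table)


def _orthogonal_columns_table():
    """Three zero-mean orthogonal columns with norms 3 > 2 > 1."""
    v1 = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
    v2 = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
    v3 = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0
    X = np.column_stack([3 * v1, 2 * v2, 1 * v3])
    return SpectrumTable(X, np.array([400.0, 500.0, 600.0]), np.array([1, 1, 2, 2]))


class TestSpa:
    def test_orthogonal_columns_selected_by_descending_norm(self):
        table = _orthogonal_columns_table()
        chain = spa_chain(table.X, np.arange(3), start=0, k_max=3)
        assert chain == [0, 1, 2]

    def test_duplicate_column_never_follows_its_twin(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X[:, 0], X[:, 0], X[:, 1], X[:, 2]])  # cols 0 and 1 identical
        with pytest.warns(UserWarning, match="rank deficient"):
            chain = spa_chain(X, np.arange(4), start=0, k_max=4)
        assert 1 not in chain  # zero residual after its twin is chosen

    def test_chain_matches_gram_schmidt_oracle(self, rng):
        """Brute-force re-orthogonalization against the chosen set at every step."""
        X = rng.normal(size=(12, 8))

        def oracle_chain(start, k_max):
            V = X - X.mean(axis=0)
            chain = [start]
            for _ in range(k_max - 1):
                basis = V[:, chain]
                q, _ = np.linalg.qr(basis)
                resid = V - q @ (q.T @ V)
                norms = np.linalg.norm(resid, axis=0)
                norms[chain] = -1.0
                chain.append(int(np.argmax(norms)))
            return chain

        for start in range(8):
            assert spa_chain(X, np.arange(8), start, 5) == oracle_chain(start, 5)

    def test_selection_invariant_to_candidate_permutation(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.repeat([1, 2], 10)
        table = SpectrumTable(X, np.linspace(400, 1000, 10), y)
        a = spa_select(table, candidates=np.arange(10), k_max=4, cv_folds=5)
        b = spa_select(table, candidates=np.arange(10)[::-1].copy(), k_max=4, cv_folds=5)
        assert np.array_equal(a.selected, b.selected)

    def test_empty_candidates_raise(self, rng):
        table = _orthogonal_columns_table()
        with pytest.raises(ValueError, match="empty"):
            spa_select(table, candidates=np.array([], dtype=int), k_max=1)


class TestUveSpa:
    def test_selection_always_inside_uve_retained_set(self, study_table_d2):
        uve = uve_select(study_table_d2, seed=0)
        chained = uve_spa(study_table_d2, uve_kwargs={"seed": 0})
        assert set(chained.selected) <= set(uve.selected)
        assert chained.n_selected <= uve.n_selected <= study_table_d2.n_bands

    def test_composition_equals_spa_on_uve_candidates(self, study_table_d2):
        uve = uve_select(study_table_d2, seed=0)
        direct = spa_select(study_table_d2, candidates=uve.selected,
                            k_max=min(15, uve.n_selected))
        chained = uve_spa(study_table_d2, uve_kwargs={"seed": 0})
        assert np.array_equal(direct.selected, chained.selected)

    def test_too_few_retained_bands_advise_cutoff(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 2, 3, 4, 5], 6)
        X = rng.normal(size=(30, 40))
        table = SpectrumTable(X, np.linspace(400, 1000, 40), y)
        with pytest.raises(ValueError, match="cutoff"):
            uve_spa(table, uve_kwargs={"n_lv": 3, "seed": 0, "n_noise": 400})


class TestSynchronous2dcos:
    def test_identical_spectra_give_zero_matrix(self):
        Y = np.tile(np.linspace(0, 1, 7), (5, 1))
        sync = synchronous_2dcos(Y)
        assert np.allclose(sync.matrix, 0.0)

    def test_single_band_variation_confined_to_its_diagonal_entry(self):
        Y = np.zeros((5, 7))
        Y[:, 3] = [0.0, 0.1, 0.2, 0.3, 0.4]
        sync = synchronous_2dcos(Y)
        nonzero = np.nonzero(np.abs(sync.matrix) > 1e-15)
        assert set(zip(*nonzero)) == {(3, 3)}

    def test_matches_double_loop_covariance_oracle(self, rng):
        Y = rng.normal(size=(5, 7))
        sync = synchronous_2dcos(Y)
        ref = Y.mean(axis=0)
        m = Y.shape[0]
        expected = np.empty((7, 7))
        for i in range(7):
            for j in range(7):
                expected[i, j] = sum(
                    (Y[k, i] - ref[i]) * (Y[k, j] - ref[j]) for k in range(m)
                ) / (m - 1)
        assert np.allclose(sync.matrix, expected, atol=1e-12)

    def test_symmetric_psd_with_variance_diagonal(self, rng):
        Y = rng.normal(size=(5, 9))
        sync = synchronous_2dcos(Y)
        assert np.allclose(sync.matrix, sync.matrix.T)
        assert np.linalg.eigvalsh(sync.matrix).min() >= -1e-12
        assert np.allclose(np.diag(sync.matrix), Y.var(axis=0, ddof=1))

    def test_fewer_than_two_rows_raise(self):
        with pytest.raises(ValueError):
            synchronous_2dcos(np.zeros((1, 5)))


class TestAutopeaks:
    def _sync(self, diag, wl=None):
        wl = np.linspace(400, 1000, len(diag)) if wl is None else wl
        from oleaspec.selection import SynchronousSpectrum

        return SynchronousSpectrum(matrix=np.diag(diag), wavelengths=wl)

    def test_monotone_diagonal_gives_empty_selection(self):
        result = autopeaks(self._sync(np.linspace(0, 1, 30)))
        assert result.n_selected == 0

    def test_two_isolated_bumps_found_exactly(self):
        x = np.arange(60, dtype=float)
        diag = np.exp(-0.5 * ((x - 15) / 2) ** 2) + 0.8 * np.exp(-0.5 * ((x - 45) / 2) ** 2)
        result = autopeaks(self._sync(diag))
        assert result.selected.tolist() == [15, 45]

    def test_stage_perturbation_autopeak_near_chlorophyll_band(self, study_table):
        """Raw-spectra 2D-COS puts an autopeak at the maturity-varying 672 nm dip."""
        sync = synchronous_2dcos(
            stage_mean_spectra(study_table.calibration()), study_table.wavelengths
        )
        peaks = autopeaks(sync)
        assert np.abs(peaks.wavelengths - 672.0).min() <= 10.0
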