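"""PLS-DA / PCA-DA contracts: PLS1 correctness, CV dimension choice, tie rules."""

from __future__ import annotations

import numpy as np
import pytest

from oleaspec import (
    ClassifierModel,
    SpectrumTable,
    cv_curve,
    pcada_fit,
    pcada_predict,
    plsda_fit,
    plsda_predict,
    venetian_folds,
)
from oleaspec.classifiers import pls1_nipals


def test_venetian_folds_take_every_kth_row():
    folds = venetian_folds(23, 10)
    assert folds[0].tolist() == [0, 10, 20]
    assert folds[9].tolist() == [9, 19]
    joined = np.sort(np.concatenate(folds))
    assert np.array_equal(joined, np.arange(23))


def test_pls1_matches_sklearn_reference(rng):
    """Independent cross-check of the NIPALS implementation."""
    from sklearn.cross_decomposition import PLSRegression

    X = rng.normal(size=(30, 12))
    y = rng.normal(size=30)
    B, b0 = pls1_nipals(X, y, 6)
    for k in (1, 2, 4, 6):
        ref = PLSRegression(n_components=k, scale=False).fit(X, y).predict(X).ravel()
        assert np.allclose(X @ B[:, k - 1] + b0[k - 1], ref, atol=1e-10)


def test_pls1_single_predictor_equals_univariate_least_squares(rng):
    x = rng.normal(size=(25, 1))
    y = 2.0 * x.ravel() + 1.0 + rng.normal(scale=0.1, size=25)
    B, b0 = pls1_nipals(x, y, 1)
    slope = np.cov(x.ravel(), y, ddof=1)[0, 1] / np.var(x.ravel(), ddof=1)
    assert B[0, 0] == pytest.approx(slope, abs=1e-10)
    assert b0[0] == pytest.approx(y.mean() - slope * x.mean(), abs=1e-10)


def _separable_table(n_per_class=10, n_bands=6, offset=10.0):
    """Two classes whose spectra differ by a large constant offset in one band."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(2 * n_per_class, n_bands))
    y = np.repeat([1, 2], n_per_class)
    X[y == 2, 3] += offset
    order = rng.permutation(len(y))
    return SpectrumTable(X[order], np.linspace(400, 1000, n_bands), y[order])


def test_separable_classes_reach_perfect_calibration_at_one_lv():
    table = _separable_table()
    model = plsda_fit(table, max_lv=5, cv_folds=10)
    assert model.n_components == 1
    labels, _ = plsda_predict(model, table.X)
    assert np.array_equal(labels, table.y)


def test_tied_responses_resolve_to_lowest_stage():
    model = ClassifierModel(
        method="plsda",
        classes=np.arange(1, 6),
        n_components=1,
        coef=np.zeros((3, 5)),
        intercept=np.array([0.9, 0.9, 0.1, 0.0, 0.0]),
        wavelengths=np.array([400.0, 500.0, 600.0]),
    )
    labels, scores = plsda_predict(model, np.zeros((1, 3)))
    assert labels[0] == 1
    assert np.allclose(scores, [[0.9, 0.9, 0.1, 0.0, 0.0]])


def test_predict_is_stateless_under_row_duplication():
    table = _separable_table()
    model = plsda_fit(table, max_lv=3)
    base, _ = plsda_predict(model, table.X)
    doubled, _ = plsda_predict(model, np.vstack([table.X, table.X[:1]]))
    assert np.array_equal(doubled[: len(base)], base)


def test_responses_invariant_to_identically_zero_band():
    table = _separable_table()
    model = plsda_fit(table, max_lv=3)
    _, ref = plsda_predict(model, table.X)
    X_aug = np.hstack([table.X, np.zeros((table.n_samples, 1))])
    wl_aug = np.append(table.wavelengths, 1001.0)
    aug = SpectrumTable(X_aug, wl_aug, table.y)
    model_aug = plsda_fit(aug, max_lv=3)
    _, scores = plsda_predict(model_aug, X_aug)
    assert np.allclose(scores, ref, atol=1e-8)


def test_band_count_mismatch_raises():
    model = plsda_fit(_separable_table())
    with pytest.raises(ValueError, match="bands"):
        plsda_predict(model, np.zeros((2, 4)))


def test_single_class_raises():
    rng = np.random.default_rng(0)
    table = SpectrumTable(rng.normal(size=(12, 4)), np.arange(4.0), np.ones(12, dtype=int))
    with pytest.raises(ValueError, match="two classes"):
        plsda_fit(table)


class TestCvCurve:
    def test_single_entry_curve(self):
        curve = cv_curve(_separable_table(), max_components=1)
        assert curve.shape == (1,)

    def test_minimum_position_equals_chosen_dimension(self, study_table_d2):
        curve = cv_curve(study_table_d2, max_components=10)
        model = plsda_fit(study_table_d2, max_lv=10)
        assert model.n_components == int(np.argmin(curve)) + 1
        assert np.array_equal(model.cv_errors, curve)

    def test_curve_reaches_zero_on_separable_data(self):
        curve = cv_curve(_separable_table(), max_components=5)
        assert curve.min() == 0


class TestPcaDa:
    def _gaussian_table(self, rng, sep=8.0, K=3, n=20, p=5):
        means = rng.normal(scale=sep, size=(K, p))
        X = np.vstack([means[k] + rng.normal(size=(n, p)) for k in range(K)])
        y = np.repeat(np.arange(1, K + 1), n)
        order = rng.permutation(len(y))
        return SpectrumTable(X[order], np.linspace(400, 1000, p), y[order])

    def test_well_separated_gaussians_classify_their_means(self, rng):
        table = self._gaussian_table(rng)
        model = pcada_fit(table, max_pc=4)
        means = np.vstack([table.X[table.y == c].mean(axis=0) for c in model.classes])
        assert np.array_equal(pcada_predict(model, means), model.classes)

    def test_matches_explicit_pooled_covariance_lda_oracle(self, rng):
        """LDA on PC scores equals the closed-form pooled-covariance discriminant."""
        table = self._gaussian_table(rng, sep=3.0)
        model = pcada_fit(table, max_pc=2)
        scores = (table.X - model.pca_center) @ model.pca_loadings
        classes = model.classes
        means = np.vstack([scores[table.y == c].mean(axis=0) for c in classes])
        resid = np.vstack([scores[table.y == c] - means[i] for i, c in enumerate(classes)])
        pooled = resid.T @ resid / (len(scores) - len(classes))
        inv = np.linalg.inv(pooled)
        disc = scores @ inv @ means.T - 0.5 * np.einsum("ij,jk,ik->i", means, inv, means)
        oracle = classes[np.argmax(disc, axis=1)]
        mine = pcada_predict(model, table.X)
        assert np.mean(mine == table.y) == pytest.approx(np.mean(oracle == table.y))

    def test_shuffled_labels_give_chance_level_cv(self, rng):
        table = self._gaussian_table(rng, sep=5.0, K=5, n=20)
        shuffled = SpectrumTable(
            table.X, table.wavelengths, rng.permutation(table.y)
        )
        curve = cv_curve(shuffled, "pcada", max_components=4)
        ccr = 100.0 * (1 - curve.min() / shuffled.n_samples)
        assert ccr < 45.0  # chance for 5 balanced classes is 20%


def test_fit_and_predict_are_deterministic(study_table_d2):
    a = plsda_fit(study_table_d2, max_lv=8)
    b = plsda_fit(study_table_d2, max_lv=8)
    assert a.n_components == b.n_components
    assert np.array_equal(a.coef, b.coef)
    pa, _ = plsda_predict(a, study_table_d2.prediction().X)
    pb, _ = plsda_predict(b, study_table_d2.prediction().X)
    assert np.array_equal(pa, pb)


def test_model_save_load_round_trip(tmp_path):
    table = _separable_table()
    model = plsda_fit(table)
    model.save(tmp_path / "model.npz")
    back = ClassifierModel.load(tmp_path / "model.npz")
    labels_a, _ = plsda_predict(model, table.X)
    labels_b, _ = plsda_predict(back, table.X)
    assert np.array_equal(labels_a, labels_b)
    assert back.n_components == model.n_components
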