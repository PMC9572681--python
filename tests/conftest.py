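"""Shared fixtures: small clean scenes and a session-scoped study-sized dataset."""

from __future__ import annotations

import numpy as np
import pytest

from oleaspec import SceneParams, assign_split, preprocess, simulate_spectra

#: single fixed seed for the study-scale regression fixtures
STUDY_SEED = 11


@pytest.fixture
def clean_params() -> SceneParams:
    """A noise-free, distortion-free scene: every pipeline stage is exact on it."""
    return SceneParams(
        n_rows=32,
        n_cols=32,
        ellipse_axes=(9.0, 12.0),
        noise_sd=0.0,
        scatter_slope=0.0,
        scatter_offset=0.0,
        background_level=0.0,
    )


@pytest.fixture(scope="session")
def study_table():
    """Full-size synthetic acquisition (40 fruit per stage) with a 3:1 split."""
    table = simulate_spectra(40, seed=STUDY_SEED)
    return assign_split(table, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_table_d2(study_table):
    return preprocess(study_table, "d2")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
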