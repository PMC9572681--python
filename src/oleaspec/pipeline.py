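"""End-to-end study orchestration: simulate/load -> calibrate -> segment -> extract ->
trim -> preprocess -> split 3:1 -> fit models -> comparison tables.

Leakage discipline: preprocessing is strictly per-spectrum (no cross-sample
statistics), splits are assigned once per seed, and every fitting or
selection routine operates on the calibration rows only — prediction rows
are first touched when a fitted model scores them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import pcada_fit, plsda_fit
from .evaluation import evaluate_splits
from .pca import loading_peaks, pca_fit
from .preprocessing import PREPROCESSORS, preprocess, trim_bands
from .selection import autopeaks, stage_mean_spectra, synchronous_2dcos, uve_spa
from .selection_result import SelectionResult
from .spectra import SpectrumTable, assign_split
from .synthetic import SceneParams, simulate_spectra

__all__ = ["PipelineConfig", "prepare_table", "run_full_comparison", "run_selection_comparison"]

MODELS = ("plsda", "pcada")
SELECTIONS = ("pc_loadings", "2dcos", "uve_spa", "full")


@dataclass
class PipelineConfig:
    """Configuration of one study run.

    Either ``n_per_stage`` (synthetic acquisition) or ``spectra_csv`` (a
    previously extracted SpectrumTable) supplies the data.  The seed governs
    every stochastic step: scene generation and the random 3:1 split.
    """

    n_per_stage: int = 40
    scene_params: SceneParams | None = None
    spectra_csv: str | Path | None = None
    preprocessing: str = "d2"
    model: str = "plsda"
    selection: str = "uve_spa"
    prediction_fraction: float = 0.25
    cv_folds: int = 10
    max_components: int = 20
    seed: int = 0
    trim: tuple[float, float] = (400.0, 1000.0)
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.preprocessing not in PREPROCESSORS:
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.selection not in SELECTIONS:
            raise ValueError(f"unknown selection {self.selection!r}")


def prepare_table(config: PipelineConfig) -> SpectrumTable:
    """Acquire (or load) spectra, trim bands, and assign the 3:1 split."""
    if config.spectra_csv is not None:
        table = SpectrumTable.from_csv(config.spectra_csv)
    else:
        table = simulate_spectra(
            config.n_per_stage, params_base=config.scene_params, seed=config.seed
        )
    table = trim_bands(table, *config.trim)
    if table.split is None:
        table = assign_split(
            table, prediction_fraction=config.prediction_fraction, seed=config.seed
        )
    return table


def _fit_and_score(table: SpectrumTable, model_name: str, config: PipelineConfig) -> dict:
    if model_name == "plsda":
        model = plsda_fit(table, max_lv=config.max_components, cv_folds=config.cv_folds)
    else:
        model = pcada_fit(table, max_pc=config.max_components, cv_folds=config.cv_folds)
    reports = evaluate_splits(model, table)
    return {
        "n_components": model.n_components,
        "ccr_calibration": reports["calibration"].overall_ccr,
        "ccr_cross_validation": reports["cross_validation"].overall_ccr,
        "ccr_prediction": reports["prediction"].overall_ccr,
        "_model": model,
        "_reports": reports,
    }


def run_full_comparison(config: PipelineConfig, table: SpectrumTable | None = None) -> pd.DataFrame:
    """Model x preprocessing grid on identical splits.

    Fits PLS-DA and PCA-DA under each of the five pre-treatments (none, SNV,
    max-min normalization, 1st and 2nd SG derivative) on the same calibration
    rows and reports calibration / cross-validation / prediction CCRs with
    the chosen latent dimension.  Deterministic per seed.
    """
    base = table if table is not None else prepare_table(config)
    rows = []
    for model_name in MODELS:
        for prep in ("none", "snv", "normalization", "d1", "d2"):
            scored = _fit_and_score(preprocess(base, prep), model_name, config)
            rows.append(
                {
                    "model": model_name,
                    "preprocessing": prep,
                    "n_components": scored["n_components"],
                    "ccr_calibration": scored["ccr_calibration"],
                    "ccr_cross_validation": scored["ccr_cross_validation"],
                    "ccr_prediction": scored["ccr_prediction"],
                }
            )
    df = pd.DataFrame(rows)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "full_comparison.csv", index=False)
    return df


def _select_bands(
    table: SpectrumTable, method: str, config: PipelineConfig
) -> SelectionResult | None:
    """Run one selection method on the calibration split only."""
    cal = table.calibration()
    if method == "full":
        return None
    if method == "pc_loadings":
        model = pca_fit(cal, k=min(3, cal.n_samples - 1, cal.n_bands))
        return loading_peaks(model, n_pcs=model.k)
    if method == "2dcos":
        sync = synchronous_2dcos(stage_mean_spectra(cal), cal.wavelengths)
        return autopeaks(sync)
    if method == "uve_spa":
        return uve_spa(table, cv_folds=config.cv_folds,
                       uve_kwargs={"seed": config.seed})
    raise ValueError(f"unknown selection {method!r}")


def run_selection_comparison(
    config: PipelineConfig,
    table: SpectrumTable | None = None,
    methods: tuple[str, ...] = SELECTIONS,
) -> pd.DataFrame:
    """Simplified-model table: selection method -> band count, dimension, CCRs.

    Each method selects wavelengths from the preprocessed calibration spectra
    (2nd derivative by default), then a PLS-DA model is refitted on the
    selected bands and scored on the untouched prediction split.  The
    ``full`` row is the matching full-spectrum model for reference.
    """
    base = table if table is not None else prepare_table(config)
    prepped = preprocess(base, config.preprocessing)
    rows = []
    selections: dict[str, SelectionResult | None] = {}
    for method in methods:
        sel = _select_bands(prepped, method, config)
        selections[method] = sel
        sub = prepped if sel is None else prepped.select_bands(sel.selected)
        scored = _fit_and_score(sub, "plsda", config)
        rows.append(
            {
                "selection": method,
                "n_wavelengths": sub.n_bands,
                "n_components": scored["n_components"],
                "ccr_calibration": scored["ccr_calibration"],
                "ccr_cross_validation": scored["ccr_cross_validation"],
                "ccr_prediction": scored["ccr_prediction"],
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["selections"] = selections
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "selection_comparison.csv", index=False)
        for name, sel in selections.items():
            if sel is not None:
                sel.to_json(out / f"selection_{name}.json")
    return df
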