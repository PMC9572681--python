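"""SpectrumTable: the n_samples x n_bands matrix all models consume."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectrumTable", "assign_split"]

CALIBRATION = "calibration"
PREDICTION = "prediction"


@dataclass
class SpectrumTable:
    """Mean spectra of a set of samples, with maturity labels and an optional split flag.

    X columns are ordered by increasing wavelength; ``y`` holds ordinal stage
    labels (1..5 in the standard five-stage design); ``split`` flags each row
    as ``"calibration"`` or ``"prediction"`` once :func:`assign_split` has run.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    y: np.ndarray
    ids: np.ndarray | None = None
    split: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != len(self.wavelengths):
            raise ValueError("X column count does not match wavelength vector")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label vector length does not match X rows")
        if self.ids is None:
            self.ids = np.array([f"s{i:04d}" for i in range(self.X.shape[0])])
        else:
            self.ids = np.asarray(self.ids)
        if self.split is not None:
            self.split = np.asarray(self.split)
            bad = set(np.unique(self.split)) - {CALIBRATION, PREDICTION}
            if bad:
                raise ValueError(f"unknown split flags {bad}")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset(self, index: np.ndarray) -> "SpectrumTable":
        """Row subset preserving order (boolean or integer index)."""
        index = np.asarray(index)
        return SpectrumTable(
            X=self.X[index],
            wavelengths=self.wavelengths.copy(),
            y=self.y[index],
            ids=self.ids[index],
            split=None if self.split is None else self.split[index],
            meta=dict(self.meta),
        )

    def calibration(self) -> "SpectrumTable":
        """Rows flagged as the calibration set (the whole table if no split is set)."""
        if self.split is None:
            return self
        return self.subset(self.split == CALIBRATION)

    def prediction(self) -> "SpectrumTable":
        if self.split is None:
            raise ValueError("table carries no split flags; call assign_split first")
        return self.subset(self.split == PREDICTION)

    def with_X(self, X: np.ndarray, wavelengths: np.ndarray | None = None) -> "SpectrumTable":
        """Copy with a new spectra matrix (same rows), e.g. after preprocessing."""
        wl = self.wavelengths if wavelengths is None else np.asarray(wavelengths, float)
        return replace(self, X=np.asarray(X, float), wavelengths=wl)

    def select_bands(self, indices: np.ndarray) -> "SpectrumTable":
        """Column subset by band index (kept sorted by wavelength)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return replace(self, X=self.X[:, idx], wavelengths=self.wavelengths[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"{w:.2f}" for w in self.wavelengths])
        df.insert(0, "sample_id", self.ids)
        df.insert(1, "stage", self.y)
        if self.split is not None:
            df.insert(2, "split", self.split)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c not in ("sample_id", "stage", "split")]
        return cls(
            X=df[band_cols].to_numpy(float),
            wavelengths=np.array([float(c) for c in band_cols]),
            y=df["stage"].to_numpy(int),
            ids=df["sample_id"].to_numpy(),
            split=df["split"].to_numpy() if "split" in df.columns else None,
        )


def assign_split(
    table: SpectrumTable,
    prediction_fraction: float = 0.25,
    seed: int = 0,
    stratify: bool = True,
) -> SpectrumTable:
    """Randomly flag rows calibration/prediction (default 3:1), stratified by stage.

    Stratification keeps the class balance of the full design in both sets, so
    a five-stage study with equal class sizes yields equal per-stage counts in
    the prediction set.
    """
    if not 0.0 < prediction_fraction < 1.0:
        raise ValueError("prediction_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = table.n_samples
    split = np.full(n, CALIBRATION, dtype=object)
    if stratify:
        for cls in table.classes:
            idx = np.flatnonzero(table.y == cls)
            n_pred = int(round(len(idx) * prediction_fraction))
            split[rng.choice(idx, size=n_pred, replace=False)] = PREDICTION
    else:
        n_pred = int(round(n * prediction_fraction))
        split[rng.choice(n, size=n_pred, replace=False)] = PREDICTION
    return replace(table, split=np.asarray(split, dtype=object))
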