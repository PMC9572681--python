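"""Shared result container for all wavelength-selection methods."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SelectionResult"]


@dataclass
class SelectionResult:
    """Ordered selected band indices with method name and diagnostics.

    ``selected`` holds unique band indices sorted ascending, ``wavelengths``
    the corresponding nm values.  ``diagnostics`` carries method-specific
    extras: the stability vector and cutoff for UVE, the RMSE-vs-k curve and
    selection order for SPA, the synchronous matrix for 2D-COS.
    """

    method: str
    selected: np.ndarray
    wavelengths: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected band indices must be unique")
        if not np.all(np.diff(self.selected) > 0) and len(self.selected) > 1:
            raise ValueError("selected band indices must be sorted ascending")
        if len(self.wavelengths) != len(self.selected):
            raise ValueError("wavelengths and selected indices differ in length")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json(self, path: str | Path | None = None) -> str:
        def _clean(value):
            if isinstance(value, np.ndarray):
                return value.tolist()
            if isinstance(value, (np.floating, np.integer)):
                return value.item()
            if isinstance(value, dict):
                return {k: _clean(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [_clean(v) for v in value]
            return value

        payload = json.dumps(
            {
                "method": self.method,
                "selected": self.selected.tolist(),
                "wavelengths": self.wavelengths.tolist(),
                "diagnostics": _clean(self.diagnostics),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload
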