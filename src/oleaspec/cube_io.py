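"""Hypercube container, minimal ENVI-style I/O, and black/white reflectance calibration.

A hypercube is stored rows x cols x bands with a strictly increasing
wavelength vector (nm).  Calibrated reflectance is kept as a fraction
(1.0 = 100% reflectance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Hypercube", "read_cube", "write_cube", "calibrate"]

_DTYPE_TO_ENVI = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_ENVI_TO_DTYPE = {4: np.dtype("float32"), 5: np.dtype("float64")}


@dataclass
class Hypercube:
    """A rows x cols x bands reflectance (or raw-count) image with its wavelength grid.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
    wavelengths : ndarray, shape (bands,)
        Band centers in nm, strictly increasing.
    meta : dict
        Free-form metadata (sample_id, stage, dead-pixel report, ...).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"hypercube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band axis {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm`` (must lie within the grid range)."""
        wl = self.wavelengths
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise ValueError(
                f"requested wavelength {wavelength_nm} nm outside grid "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return int(np.argmin(np.abs(wl - wavelength_nm)))

    def plane(self, wavelength_nm: float) -> np.ndarray:
        """Single-band image at the band nearest ``wavelength_nm``."""
        return self.data[:, :, self.band_index(wavelength_nm)]


def write_cube(cube: Hypercube, path: str | Path, interleave: str = "bil") -> Path:
    """Write a cube as an ENVI-style header/binary pair.

    ``path`` may point at either file of the pair; the header gets a ``.hdr``
    suffix and the binary a ``.img`` suffix.  Interleave is ``bil`` or ``bsq``.
    Returns the header path.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    base = Path(path).with_suffix("")
    hdr_path, img_path = base.with_suffix(".hdr"), base.with_suffix(".img")
    data = np.ascontiguousarray(cube.data)
    if data.dtype not in _DTYPE_TO_ENVI:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    if interleave == "bil":  # (lines, bands, samples)
        ordered = np.transpose(data, (0, 2, 1))
    else:  # bsq: (bands, lines, samples)
        ordered = np.transpose(data, (2, 0, 1))
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {oleaspec hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[data.dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    for key in ("sample_id", "stage"):
        if key in cube.meta:
            lines.append(f"{key} = {cube.meta[key]}")
    hdr_path.write_text("\n".join(lines) + "\n")
    ordered.astype(data.dtype).tofile(img_path)
    return hdr_path


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    # fold brace-delimited multi-line values onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI-style header/binary pair written by :func:`write_cube` or compatible.

    Supports BIL and BSQ interleave and float32/float64 data.  Raises on a
    missing wavelength field or when the header geometry disagrees with the
    binary file size.
    """
    base = Path(path).with_suffix("")
    hdr_path, img_path = base.with_suffix(".hdr"), base.with_suffix(".img")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength field")
    if dtype_code not in _ENVI_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = _ENVI_TO_DTYPE[dtype_code]
    wl = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} ").split(",") if tok.strip()]
    )
    if len(wl) != bands:
        raise ValueError(f"header lists {len(wl)} wavelengths for {bands} bands")
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"binary size {raw.size} does not match header geometry "
            f"{rows}x{cols}x{bands}"
        )
    if interleave == "bil":
        data = np.transpose(raw.reshape(rows, bands, cols), (0, 2, 1))
    elif interleave == "bsq":
        data = np.transpose(raw.reshape(bands, rows, cols), (1, 2, 0))
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    meta = {k: fields[k] for k in ("sample_id", "stage") if k in fields}
    return Hypercube(data=np.ascontiguousarray(data), wavelengths=wl, meta=meta)


def calibrate(
    raw: Hypercube,
    white: Hypercube,
    dark: Hypercube,
    reduce_references: str = "none",
) -> Hypercube:
    """Black-and-white reflectance calibration: ``R = (raw - dark) / (white - dark)``.

    The white frame is the ~100% reflectance reference (e.g. a Teflon plate),
    the dark frame the ~0% reference (capped lens).  By default references are
    used per pixel (flat-field); ``reduce_references="per_band"`` collapses
    white and dark to their per-band spatial means first.

    Dead pixels, where ``white - dark <= 0``, yield 0.0 instead of infinities
    and are reported in ``meta["dead_pixel_count"]`` (plus the affected band
    indices in ``meta["dead_bands"]``).
    """
    for name, ref in (("white", white), ("dark", dark)):
        if ref.shape != raw.shape:
            raise ValueError(f"{name} reference shape {ref.shape} != raw shape {raw.shape}")
        if not np.allclose(ref.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} reference wavelength grid differs from raw")
    w, d = white.data, dark.data
    if reduce_references == "per_band":
        w = np.broadcast_to(w.mean(axis=(0, 1)), raw.shape)
        d = np.broadcast_to(d.mean(axis=(0, 1)), raw.shape)
    elif reduce_references != "none":
        raise ValueError(f"unknown reduce_references mode {reduce_references!r}")
    denom = w - d
    dead = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(dead, 0.0, (raw.data - d) / np.where(dead, 1.0, denom))
    meta = dict(raw.meta)
    meta["dead_pixel_count"] = int(dead.sum())
    if dead.any():
        meta["dead_bands"] = sorted(int(b) for b in np.unique(np.nonzero(dead)[2]))
    return Hypercube(data=refl, wavelengths=raw.wavelengths.copy(), meta=meta)
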