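"""Simulate one fruit scene, write/read it as ENVI, and calibrate to reflectance.

The generator renders raw sensor counts from a true reflectance scene via
raw = dark + (white - dark) * R, so the black/white calibration
R = (raw - dark) / (white - dark) is exercised for real, not bypassed.
"""

import tempfile

import numpy as np

from oleaspec import SceneParams, calibrate, generate_scene, read_cube, write_cube

params = SceneParams(stage=2, seed=42)
scene = generate_scene(params)

with tempfile.TemporaryDirectory() as tmp:
    write_cube(scene.raw, f"{tmp}/raw", interleave="bil")
    raw_back = read_cube(f"{tmp}/raw")

reflectance = calibrate(raw_back, scene.white, scene.dark)
fruit = reflectance.data[scene.truth.values]
background = reflectance.data[~scene.truth.values]

print(f"scene: {scene.raw.shape[0]}x{scene.raw.shape[1]} px, {scene.raw.n_bands} bands "
      f"({reflectance.wavelengths[0]:.0f}-{reflectance.wavelengths[-1]:.0f} nm)")
print(f"fruit pixels: {scene.truth.n_foreground}, dead pixels: {reflectance.meta['dead_pixel_count']}")
print(f"fruit reflectance range:      {fruit.min():.3f} .. {fruit.max():.3f}")
print(f"background reflectance range: {background.min():.3f} .. {background.max():.3f}")
i672 = reflectance.band_index(672.0)
print(f"mean fruit reflectance at 672 nm: {fruit[:, i672].mean():.3f} "
      "(the chlorophyll absorption dip; it shallows as the fruit ripens)")
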