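"""Segment the fruit from the background and extract its mean spectrum.

Band math (862 nm minus 416 nm) gives a high-contrast image because fruit is
bright in the NIR and dark at the Soret absorption; thresholding at 0.1
reflectance isolates the fruit, and the mean over the masked pixels is the
one spectrum that represents the sample downstream.
"""

import numpy as np

from oleaspec import SceneParams, band_math, generate_scene, mean_spectrum, threshold_mask
from oleaspec.segmentation import band_math_report
from oleaspec.synthetic import true_spectrum

params = SceneParams(stage=4, seed=7)
scene = generate_scene(params)
cal = scene.calibrated()

image = band_math(cal, wl_high=862.0, wl_low=416.0)
report = band_math_report(cal, 862.0, 416.0)
mask = threshold_mask(image, threshold=0.1)
spectrum = mean_spectrum(cal, mask)

agreement = np.mean(mask.values == scene.truth.values)
err = np.abs(spectrum - true_spectrum(params)).max()
print(f"band math used bands at {report['band_wavelengths'][0]:.1f} and "
      f"{report['band_wavelengths'][1]:.1f} nm (nearest to the requested 862/416)")
print(f"mask: {mask.n_foreground} foreground px, {100*agreement:.2f}% agreement with ground truth")
print(f"max per-band gap between extracted and true spectrum: {err:.4f} reflectance")
print("(pixel noise and scatter average out over the fruit; the gap shrinks as 1/sqrt(n_pixels))")
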