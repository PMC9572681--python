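"""Pre-treat extracted spectra and explore them with PCA.

SNV and max-min normalization remove per-spectrum gain/offset distortions;
Savitzky-Golay derivatives (window 7, quadratic) remove baselines and sharpen
overlapping bands.  PCA then shows how much structure the stages share and
which wavelengths drive the leading components.
"""

import numpy as np

from oleaspec import loading_peaks, pca_fit, preprocess, simulate_spectra

table = simulate_spectra(20, seed=5)
print(f"simulated {table.n_samples} samples x {table.n_bands} bands")

for method in ("snv", "normalization", "d2"):
    X = preprocess(table, method).X
    print(f"{method:13s} -> row mean {X[0].mean():8.3f}, row range "
          f"[{X[0].min():7.3f}, {X[0].max():7.3f}]")

model = pca_fit(table, k=3)
print("explained variance (PC1..PC3): "
      + ", ".join(f"{v:.2f}%" for v in model.explained_pct))
peaks = loading_peaks(model, n_pcs=3)
print(f"loading-line extrema picked {peaks.n_selected} candidate wavelengths:")
print("  " + ", ".join(f"{w:.0f}" for w in peaks.wavelengths) + " nm")
print("(peaks/valleys of the first loading lines mark bands that separate stages)")
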