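"""Select key maturity wavelengths three ways: UVE, UVE+SPA, and 2D-COS.

UVE keeps bands whose PLS regression coefficients are more stable than
artificial noise variables; SPA then prunes the survivors to a minimally
collinear subset by successive orthogonal projections.  Synchronous 2D-COS
treats maturity stage as the perturbation and reads sensitive bands off the
autopeaks of the covariance diagonal.  All three should flag the 672 nm
chlorophyll region, the strongest maturity marker.
"""

import numpy as np

from oleaspec import (
    assign_split,
    autopeaks,
    preprocess,
    simulate_spectra,
    synchronous_2dcos,
    uve_select,
    uve_spa,
)
from oleaspec.selection import stage_mean_spectra

table = assign_split(simulate_spectra(40, seed=1), seed=1)
d2 = preprocess(table, "d2")

uve = uve_select(d2, seed=1)
print(f"UVE retained {uve.n_selected}/{d2.n_bands} bands "
      f"(stability cutoff {uve.diagnostics['cutoff']:.1f}, from {uve.diagnostics['n_noise']} noise variables)")

chained = uve_spa(d2, uve_kwargs={"seed": 1})
print(f"UVE+SPA kept {chained.n_selected} bands: "
      + ", ".join(f"{w:.0f}" for w in chained.wavelengths) + " nm")

sync = synchronous_2dcos(stage_mean_spectra(d2.calibration()), d2.wavelengths)
peaks = autopeaks(sync)
print(f"2D-COS autopeaks: " + ", ".join(f"{w:.0f}" for w in peaks.wavelengths) + " nm")

for name, sel in (("UVE+SPA", chained), ("2D-COS", peaks)):
    print(f"{name} nearest band to the 672 nm chlorophyll dip: "
          f"{np.abs(sel.wavelengths - 672).min():.1f} nm away")
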