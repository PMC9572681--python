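# Methods

## The problem and the data model

A five-stage fruit-maturity study with visible/NIR hyperspectral imaging
produces, per sample, a reflectance hypercube (rows × cols × bands) plus
white and dark reference frames. The working spectral range is 400–1000 nm;
the default grid is 119 evenly spaced bands across it. Everything downstream
operates on one mean spectrum per fruit, extracted from the segmented fruit
region, collected into a SpectrumTable (n_samples × n_bands with ordinal
stage labels 1–5 and a calibration/prediction split flag).

## Reflectance calibration

`I_c = (I_r − I_d)/(I_w − I_d)`, per pixel by default (flat-field); an
option collapses the references to per-band spatial means, since real
studies differ on whether the white tile is used as a full frame or a
spectrum. The ratio is invariant to any affine rescaling applied to all
three frames, which is exactly its job: removing illumination gain and dark
current. Dead pixels (`I_w ≤ I_d`) are reported in metadata and emitted as
0.0 — downstream masking needs finite numbers, not infinities.

## Segmentation

"Image at λ nm" resolves to the nearest grid band, and the bands actually
used are reported, because named wavelengths (416, 672, 862, 979 nm) rarely
sit exactly on an instrument grid. The difference image (862 − 416 nm) is
thresholded strictly at 0.1 reflectance (a pixel exactly at threshold is
background). No morphological cleanup is applied by default. The mean
spectrum averages foreground pixels only; zeroed background can never leak
into it, and an empty mask is an error rather than a NaN spectrum.

## Preprocessing

All four pre-treatments are strictly per-spectrum, so they cannot leak
information across the calibration/prediction split:

- **SNV**: row-center, divide by row sd (n−1).
- **Max-min normalization**: map each row onto [0, 1] exactly.
- **SG derivatives**: window 7, polynomial order 2, derivative order 1 or 2.
  Edge points evaluate the edge-window polynomial (scipy's `interp` mode),
  so no bands are lost and the table keeps its 119 columns. Derivatives are
  per band-index step, not per nm: classification is invariant to a global
  scale, and instrument grids make the nm step ambiguous.

Band trimming (default 400–1000 nm) runs before preprocessing.

## Classifiers

**PLS-DA.** One PLS1 regression per class against its {0,1} indicator
column; assignment is argmax over the five responses, exact ties to the
lowest stage. The PLS1 core is an in-package NIPALS: for a single response
the inner iteration collapses to a finite sequence of rank-one deflations,
and coefficients are available for every truncation 1..k from one pass —
which is what makes the CV curves and the UVE submodels cheap. Predictors
are mean-centered only (no autoscaling); class coding and assignment rule
are package choices where the literature is silent.

**PCA-DA.** PCA on the calibration spectra, then linear discriminant
analysis with equal priors and pooled within-class covariance on the first p
un-rotated score columns.

**Dimension choice.** Venetian-blinds 10-fold CV on the calibration rows:
fold f holds rows f, f+10, f+20, … in table order (the table's row order
defines the folds — documented because the scheme's name specifies the
stride, not the ordering). The chosen dimension is the smallest one
minimizing the CV misclassification count; a PRESS criterion on the
indicator responses is available as a flag. Maximum dimension defaults
to 20.

## Wavelength selection

**UVE.** The spectra matrix is augmented with as many uniform noise columns
as real bands, scaled by 1e−10 so they are numerically negligible but
rank-visible. Leave-one-out PLS1 submodels are fitted per class indicator;
each (variable, class) pair gets a stability mean/sd across the n submodels,
and a real band survives if any class's |stability| exceeds the symmetric
cutoff — by default the maximum |stability| over the noise block, with a
percentile option. Two interpretation choices matter and are deliberate:
stability is computed within class (pooling classes into one series would
read between-class coefficient differences as instability and eliminate
precisely the discriminative bands), and the submodel dimension defaults to
the CV-optimal LV of a full-spectrum PLS-DA on the same rows
(over-dimensioned submodels fit noise, flattening the real/noise stability
contrast; at the working dimension the method retains roughly half the
bands, matching how it behaves in published practice).

**SPA.** Candidate columns are mean-centered over calibration samples. From
every possible starting band a chain grows by repeatedly adding the
candidate with maximal residual norm orthogonal to the span of the chosen
set (modified Gram–Schmidt, exact ties to the lowest band index, truncation
with a warning on rank deficiency). Each chain prefix of length k is scored
by venetian-blinds CV RMSE of a PLS-DA restricted to those k bands (latent
dimension min(k, 10)); the global minimum wins, ties to smaller k. Scores
are memoized per unique band subset, which collapses the cost since chains
from different starts largely coincide. Candidates are sorted internally, so
the result is invariant to the caller's candidate order.

**UVE+SPA.** Composition: UVE's retained set becomes SPA's candidates; the
final selection is provably a subset of the retained set. Fewer than two
retained bands raises an error advising a relaxed cutoff.

**2D-COS.** The synchronous spectrum is `Φ = Ỹᵀ Ỹ/(m−1)` where Ỹ are the
five stage-mean spectra minus their perturbation mean (the conventional
reference choice; class means rather than all spectra form the perturbation
series). Φ is symmetric PSD with per-band variance on the diagonal;
autopeaks are diagonal local maxima passing a prominence filter.

**Prominence defaults.** Extrema filters (PC loading lines, 2D-COS
diagonal) default to 10% of the line's range — unstated in the literature
this mirrors, configurable here.

## The synthetic acquisition

The generator emulates the *structure* such a study assumes, not any
particular instrument: an ellipsoidal bright fruit on a dark belt
(background reflectance ≤ 0.05), a smooth base curve low in the visible and
high in the NIR, and Gaussian absorption features at 416, 672, 862, 979 nm.
Scenes are rendered as raw counts via `raw = dark + (white − dark) · R` with
a smooth lamp spectrum and a mild spatial flat-field slope, so calibration
is genuinely exercised and inverts the construction exactly in the
noise-free case.

Stage structure: the 672 nm chlorophyll dip depth decreases strictly and
convexly with stage (0.180 → 0.042); the 416/862/979 nm features change
non-monotonically at comparable scales, the way pigment, moisture and
carbohydrate indices move through ripening. This makes the five stage
spectra a well-spread simplex in band space rather than points on a line —
a deliberate choice: with collinear class means, regression on class
indicators (PLS-DA) suffers the classic middle-class masking problem and no
amount of latent variables fixes it, which is not the regime the method is
used in.

Noise model, per scene: per-pixel multiplicative scatter `(1 + 0.1·u)`,
per-pixel additive baseline `0.01·v`, i.i.d. pixel noise sd 0.01. Per
sample (dataset level): dip-depth jitter sd 0.005, gain jitter sd 0.03,
offset jitter sd 0.003, ellipse geometry jitter. The per-sample gain/offset
is the between-acquisition distortion SNV and derivatives exist to remove;
per-pixel scatter alone would average out in the mean spectrum. Defaults
put full-spectrum prediction CCR in the mid-90s — the high-but-imperfect
regime published full-spectrum models report — with misclassification
concentrated between adjacent stages.

What the generator does **not** emulate: radiometric response of a real
camera, fruit surface texture and specularities, shadows, multi-fruit
scenes, cracked/overripe fruit. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under the stated
statistical structure, not instrument-level performance on real orchards.

Problem sizes: dataset-scale runs use 40 fruit per stage (200 scenes) at
32×32 px frames with streaming extraction (scene → calibrate → segment →
extract, nothing kept in memory); single-scene work uses 64×64 px. These
are the package's standard study conditions; the geometry is scaled down
from production line-scan frames since the mean-spectrum pipeline only
cares about the foreground pixel count.

## Numerical choices and degenerate inputs

- PCA loadings are sign-canonicalized (largest-magnitude element positive)
  to make results reproducible; explained variance matches the covariance
  eigendecomposition to machine precision.
- argmax assignment uses first-occurrence ties, so exact ties go to the
  lowest stage deterministically.
- PLS1 truncates gracefully when the residual matrix degenerates (constant
  response, rank-deficient predictors) by repeating the last valid
  coefficient vector; a constant response yields the intercept-only model.
- Constant spectra are rejected by SNV/normalization with the offending row
  named; empty masks, empty prediction splits, single-class tables, and
  out-of-grid wavelengths all raise explicit errors.
- Reported tables round with Python's correctly-rounded float rounding
  (numpy's scale-and-rint can flip values adjacent to ties, e.g. 0.955
  stored as 0.95499…); unrounded ratios are always retained alongside.

## Known limitations

- UVE uses leave-one-out submodels (n submodels); a Monte-Carlo resampling
  option is the natural extension for n in the thousands.
- SPA's inner RMSE model fixes its latent dimension at min(k, 10) rather
  than nesting another dimension search; with ≤ 15-band subsets this is not
  binding.
- PCA-DA relies on the SVD-based discriminant solver, which tolerates
  singular pooled covariance silently; the dimension is additionally capped
  at n − K with a warning.
- The asynchronous 2D-COS spectrum is not computed (the synchronous
  autopeaks are what band selection uses).
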