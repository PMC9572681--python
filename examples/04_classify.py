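"""Fit PLS-DA and PCA-DA maturity classifiers with venetian-blinds CV.

The latent dimension is the smallest one minimizing the cross-validated
misclassification count.  Reports cover the calibration set (resubstitution),
the CV folds, and the untouched 3:1 prediction split.
"""

from oleaspec import assign_split, evaluate_splits, pcada_fit, plsda_fit, preprocess, simulate_spectra

table = assign_split(simulate_spectra(24, seed=5), seed=5)
d2 = preprocess(table, "d2")

for name, fit in (("PLS-DA", plsda_fit), ("PCA-DA", pcada_fit)):
    model = fit(d2)
    reports = evaluate_splits(model, d2)
    print(f"{name}: {model.n_components} components "
          f"| CCR cal {reports['calibration'].overall_ccr:.1f}% "
          f"cv {reports['cross_validation'].overall_ccr:.1f}% "
          f"pred {reports['prediction'].overall_ccr:.1f}%")

model = plsda_fit(d2)
print("\nprediction-set confusion matrix (rows actual, cols predicted):")
print(evaluate_splits(model, d2)["prediction"].to_text())
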