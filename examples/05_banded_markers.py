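"""Banded single-marker analysis and inter-marker correlation.

Some blood markers separate patients from healthy subjects with *two*
thresholds: healthy values occupy an interval and disease values fall on
both flanks. A single cut-point cannot capture that pattern, but the
radial-kernel SVM (and an explicit two-threshold interval rule) can. This
example fits the interval classifier to a planted banded marker and shows
why the flank structure also produces near-perfect inter-marker
correlations within the AD group.
"""

from svmpanel import (
    SyntheticSpec,
    fit_banded,
    floor_log_transform,
    generate_cohort,
    loocv_accuracy,
    panel_correlations,
)

spec = SyntheticSpec(age_effect_sd=0.0, gender_effect_sd=0.0)
ds, truth = generate_cohort(spec, seed=5)
log = floor_log_transform(ds)
fid = truth.banded_ids[0]
values = log.values[fid].to_numpy()
labels = log.binary_labels()

fit = fit_banded(values, labels)
print(f"marker {fid}: healthy interval recovered as "
      f"({fit.lower:.2f}, {fit.upper:.2f}] log2 units")
print(f"  interval-rule accuracy        = {fit.interval_accuracy:.3f}")
print(f"  best single-threshold accuracy = {fit.best_single_threshold_accuracy:.3f}")
print(f"  banded pattern detected: {fit.is_banded}")

svm_acc = loocv_accuracy(values.reshape(-1, 1), labels)
print(f"  radial-SVM LOOCV accuracy      = {svm_acc:.3f}  "
      "(the kernel learns both boundaries on its own)")

corr = panel_correlations(log, truth.banded_ids)
print("\nplanted-pair Pearson r (AD group):",
      round(corr["AD"].iloc[0, 1], 3),
      "| (healthy group):", round(corr["CONTROL"].iloc[0, 1], 3))
print("AD samples share the same latent flank, so their marker values move "
      "together; healthy values are independent band noise.")
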