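"""Evaluate a panel with the repeated stratified-split metric battery.

Trains on 30 AD + 30 healthy randomly drawn samples, tests on the held-out
remainder, and repeats 1000 times (5000 in a full analysis). The averaged
panel of confusion-derived metrics is how panel quality is reported:
sensitivity, specificity, PPV, NPV, their complements FDR and FOR, accuracy
and the AUC of the decision scores.
"""

from svmpanel import (
    SplitScheme,
    SyntheticSpec,
    correct_age_gender,
    floor_log_transform,
    generate_cohort,
    repeated_split_cv,
    svmfs,
)

ds, truth = generate_cohort(SyntheticSpec(), seed=3)
corrected, _ = correct_age_gender(floor_log_transform(ds))
panel = svmfs(corrected).selected
print(f"evaluating panel {panel}")

result = repeated_split_cv(corrected, panel,
                           scheme=SplitScheme(n_train_pos=30, n_train_neg=30,
                                              n_repeats=1000, seed=0))
for name, value in result.mean_metrics.as_dict().items():
    print(f"  mean {name:12s} {value:.4f}")
print(f"(means over {len(result.per_repeat)} random 60-sample training draws; "
      "each tests on the remaining 10 AD + 20 healthy)")
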