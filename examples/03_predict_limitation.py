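"""Predict Fe limitation from environmental covariates.

Generates stream covariates whose Fe presence/absence label follows the
planted rule "DRP > 5.6 ug/L and N_DEP < 3.6 kg N/ha/yr" (with 5% label
noise), imputes the few missing cells by predictive mean matching, fits a
grid-tuned random forest, and reads thresholds off the partial-dependence
curves of the top predictors.
"""

from colimstat import ImputationSpec, TuningGrid, fit_presence_model, impute_pmm
from colimstat.synthetic import FE_RULE, generate_covariates

stream_ids = [f"S{i:03d}" for i in range(200)]
covariates, labels = generate_covariates(stream_ids, rules=(FE_RULE,), seed=7)

wide = impute_pmm(covariates.to_wide(), ImputationSpec(seed=7))
y = labels.set_index("stream_id")["Fe"].loc[wide.index]

# reduced tuning grid keeps this demo quick; TuningGrid() is the full search
report = fit_presence_model(
    wide, y, element="Fe", grid=TuningGrid(("sqrt",), (8, None), (250,)), seed=7
)

print(f"train misclassification (out-of-bag): {report.train_misclassification:.2f}")
print(f"test accuracy: {report.test_accuracy:.2f}  "
      f"(no-information rate {report.no_information_rate:.2f})")
print(f"well-performing: {report.well_performing}\n")
print("top predictors (mean impurity decrease):")
print(report.importance.head(4).to_string(float_format=lambda v: f"{v:.3f}"))
print("\ndetected partial-dependence thresholds:")
for feature, t in report.thresholds.items():
    if t is not None:
        print(f"  {feature}: {t.direction} near {t.value:.2f}")
print(
    "\nA well-performing model recovers the planted rule: the probability of"
    "\nFe limitation rises sharply above DRP ~5.6 and falls above N_DEP ~3.6."
)
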