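"""Random-forest severity predictor with learning-curve tuning.

Trees vote with equal weight; ties resolve toward the less severe level.
10-fold stratified cross-validation yields out-of-fold predictions for
every crash and a pooled confusion matrix.
"""

from crashsev import (
    ForestConfig,
    generate_multi_year,
    kfold_cv,
    tune_n_trees,
    washington_preset,
)

data = generate_multi_year(washington_preset(n_crashes=2000, seed=4))
config = ForestConfig(cv_folds=10, seed=4)

curve, best = tune_n_trees(data, [25, 50, 100], config)
print(curve.to_string(index=False))
print(f"selected tree count: {best}")

preds, cm = kfold_cv(data, ForestConfig(n_trees=best, cv_folds=10, seed=4))
print("\npooled out-of-fold confusion matrix (actual rows, predicted columns):")
print(cm.as_frame().to_string())
print(f"\nCV accuracy: {100 * cm.overall_accuracy():.2f}%")
print(f"always-PDO baseline: {100 * (data['severity'] == 'PDO').mean():.2f}%")
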