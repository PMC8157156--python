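"""Comprehensive-crash-cost evaluation of two severity predictors.

Raw accuracy treats every misclassification alike; the cost view prices
each severity level with its 2017 comprehensive unit cost (economic +
monetized QALY loss) and compares predicted with actual total cost.  The
two reference confusion matrices below come from a published Washington
two-year multi-vehicle evaluation set (a mixed logit and a random forest).
"""

import numpy as np

from crashsev import ConfusionMatrix, compare_models, default_cost_table, evaluation_report

rpl_counts = np.array([[1881, 918, 3], [850, 440, 3], [4, 2, 0]])
rf_counts = np.array([[2408, 419, 1], [909, 306, 1], [0, 0, 0]])

costs = default_cost_table()
print("2017 unit costs (USD):")
print(costs.as_frame().to_string(float_format="%.0f"))

rpl = evaluation_report(ConfusionMatrix(counts=rpl_counts), costs, "mixed-logit")
rf = evaluation_report(ConfusionMatrix(counts=rf_counts), costs, "random-forest")

print("\ndisplay-scale comparison (costs truncated to integers):")
print(compare_models([rpl, rf], paper_style=True).to_string())
print()
print("The forest wins on raw accuracy, but the mixed logit misprices the")
print("crash total by only ~3.6% versus ~27% — cost-weighted evaluation")
print("reverses the ranking because fatal and injury errors dominate cost.")
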