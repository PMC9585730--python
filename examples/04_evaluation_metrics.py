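"""The evaluation kit: rank-statistic AUC, regression metrics, splits, and
dataset diagnostics."""

import numpy as np

from molsent import (
    GeneratorSpec,
    auc,
    gen_molecules,
    mean_cross_similarity,
    paired_t_test,
    positive_ratio,
    q_squared,
    r_squared,
    random_split,
    rmse,
    scaffold_split,
)

# Rank-statistic ROC-AUC (mid-ranks for ties): one win, one loss -> 0.5
print("AUC:", auc([0.3, 0.8, 0.9], [1, 0, 1]))

# Regression metrics; R^2 centers TSS on the prediction mean by convention
y = np.array([2.1, 2.9, 4.2, 5.1])
t = np.array([2.0, 3.0, 4.0, 5.0])
print("RMSE:", round(rmse(y, t), 4))
print("R^2 :", round(r_squared(y, t), 4))
print("Q^2 :", round(q_squared(y, t, training_tss_reference=5.0), 4))

# Splits: random 8:1:1 vs Bemis-Murcko scaffold grouping
molecules = gen_molecules(GeneratorSpec(n_molecules=100, seed=5))
r = random_split(len(molecules), seed=0)
s = scaffold_split(molecules, seed=0)
print("random split sizes:  ", len(r.train), len(r.validation), len(r.test))
print("scaffold split sizes:", len(s.train), len(s.validation), len(s.test))
# Scaffold splits keep whole ring frameworks together, so train and test are
# structurally dissimilar — the harder, more realistic evaluation.

sim = mean_cross_similarity(
    [molecules[i] for i in s.train][:20], [molecules[i] for i in s.test][:20]
)
print("mean train->test Tanimoto similarity:", round(sim["mean"], 3))

# Dataset diagnostics and run comparison
print("positive ratio:", positive_ratio([1, 0, 0, 0]))
rmse_model_a = [0.61, 0.59, 0.63, 0.60, 0.62]
rmse_model_b = [0.66, 0.64, 0.67, 0.66, 0.65]
print("paired t-test p-value:", round(paired_t_test(rmse_model_a, rmse_model_b), 5))
# A small p-value says the RMSE difference between the two models across
# five matched runs is unlikely under the no-difference hypothesis.
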