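"""Shape statistics at study scale: Procrustes ANOVA, CVA and per-sex DFA.

Simulates the full 165-specimen two-species x two-sex dataset (group sizes
86/26/45/8), tests sex and species effects on head shape, ordinates the
four groups by canonical variate analysis and classifies females of the
two species with a leave-one-out cross-validated discriminant function.
"""

import numpy as np

from fleagm.shape_core import gpa
from fleagm.shape_stats import FactorialDesign, cva, dfa_two_group, procrustes_anova
from fleagm.synthetic import ShapeSimSpec, simulate_landmark_dataset

dataset, _ = simulate_landmark_dataset(ShapeSimSpec(seed=42))
res = gpa(dataset)
design = FactorialDesign.from_labels(dataset.labels)

anova = procrustes_anova(res.tangent, design)
print("Procrustes ANOVA (sequential SS, isotropic model):")
print(anova.to_string(index=False, float_format=lambda x: f"{x:.4g}"))

out = cva(res.tangent, design.cells(), n_perm=999, seed=0)
print(f"\ncanonical variates: {len(out.eigenvalues)}; "
      f"percent variance: {np.round(out.percent_variance, 1)} (sum 100)")
print(f"largest pairwise mean-shape permutation p: "
      f"{out.p_procrustes.values[~np.eye(4, dtype=bool)].max():.4g}")

females = dataset.labels["sex"] == "F"
dfa = dfa_two_group(res.tangent[females.to_numpy()],
                    dataset.labels.loc[females, "species"].to_numpy(),
                    n_perm=999, seed=0)
print("\nfemale C. canis vs C. orientis, leave-one-out contingency table:")
print(dfa.loo)
print(f"per-group LOO misclassification: "
      f"{(100 * dfa.loo_misclassification).round(1).to_dict()} %")
overall = 100 * (1 - (dfa.loo.values.diagonal().sum() / dfa.loo.values.sum()))
print(f"overall LOO error: {overall:.1f}%")
# A single-digit overall LOO error against a ~31% observer error rate is the
# improvement head-shape morphometrics buys over a traditional key.
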