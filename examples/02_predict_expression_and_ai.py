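"""Impute expression and allelic imbalance from fitted effect sizes.

After fitting a 2-eQTL gene, predicts each individual's log2 expression
(fold change from the cohort mean) and allelic imbalance from their phased
genotype alone, and scores both against the simulated observations with
the uncentered-denominator R^2.  A permutation audit shows the R^2 is not
an overfitting artifact.
"""

import numpy as np

from afckit import (
    SimParams,
    allelic_r2,
    expression_r2,
    fit_afc,
    normalize_log,
    observed_ai,
    permutation_control,
    predict_ai,
    simulate_cohort,
)

cohort = simulate_cohort(
    SimParams(n_individuals=400, n_eqtls=2, n_genes=1, mean_expression=800, seed=7)
)
gene = "GENE0000"
design = cohort.design_for(gene)
y = normalize_log(cohort.counts).loc[gene, design.sample_ids]

model = fit_afc(design, y, compute_ci=False)
r2_expr = expression_r2(model, design, y)

pred_ai = predict_ai(model.s, design.H1, design.H2)
ase = cohort.ase.table.set_index("sample_id")
obs_ai = np.array(
    [
        observed_ai(ase.loc[s, "hap1_count"], ase.loc[s, "hap2_count"], min_total=100)
        for s in design.sample_ids
    ]
)
r2_ai = allelic_r2(pred_ai, obs_ai)

perm = permutation_control(design, y, n_perm=100, seed=1)

print(f"expression R^2 (genotype-predicted vs observed): {r2_expr:.3f}")
print(f"allelic-imbalance R^2 ({np.sum(~np.isnan(obs_ai))} samples with "
      f">=100 ASE reads): {r2_ai:.3f}")
print(f"permutation null R^2: mean {perm.mean:+.4f} "
      f"(unpermuted {perm.r2_unpermuted:.3f})")
# The genotype explains a large share of simulated expression variation and
# allelic imbalance; after permuting sample labels the refitted model
# explains essentially nothing, so the R^2 is genuine signal.
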