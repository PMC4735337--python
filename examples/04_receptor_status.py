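"""Receptor-status prediction from single marker genes.

ER status is modelled by logistic regression on ESR1 expression alone; the
decision cutoff is chosen on the training ROC by Youden's index
(J = sensitivity + specificity - 1) and applied to held-out samples.
"""

from subtypecurves import (CohortConfig, CurveConfig, run_receptor_curve,
                           simulate_cohort, summarize_receptor_curve)

cohort = simulate_cohort(CohortConfig(n_samples=400, n_genes=500,
                                      n_informative=50, seed=4))
config = CurveConfig(training_sizes=(50, 100, 200), n_rounds=10,
                     master_seed=11)

for receptor in ("ER", "PR", "Her2"):
    records = run_receptor_curve(cohort, receptor, config)
    summary = summarize_receptor_curve(records)
    line = ", ".join("N=%d: %.3f" % (row["size"], row["accuracy_mean"])
                     for _, row in summary.iterrows())
    print(f"{receptor:5s} accuracy  {line}")

print("\nER and Her2 are nearly saturated at small N because one marker"
      "\ngene carries almost all the signal; the ceiling below 1.0 is the"
      "\nsimulated clinical label noise, which no classifier can beat.")
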