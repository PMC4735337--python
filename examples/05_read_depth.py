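"""Effect of sequencing depth on subtype classification accuracy.

Counts are binomially thinned to a target number of reads per sample,
renormalized, and the learning-curve engine is rerun at each depth.
"""

from subtypecurves import (ClassifierSpec, CohortConfig, CurveConfig,
                           DatasetDef, run_learning_curve, simulate_cohort)

cohort = simulate_cohort(CohortConfig(n_samples=300, n_genes=2000,
                                      n_informative=200,
                                      library_size_mean=2e6, seed=5))
config = CurveConfig(
    training_sizes=(150,),
    n_rounds=4,
    classifier_specs=(ClassifierSpec("nsc", {"threshold": [0.0, 1.0]}),),
    datasets=(("Panel", DatasetDef("informative_panel", panel_size=40)),),
    read_depth_grid=(10_000, 100_000, 1_000_000),
    inner_folds=3, master_seed=13)

result = run_learning_curve(cohort, config)
print(result.summary[["depth", "accuracy_mean", "accuracy_sem"]]
      .to_string(index=False))
print("\nAccuracy degrades only once thinning removes so many reads that"
      "\npanel genes drop to single-digit counts; above that, depth buys"
      "\nlittle - the motivation for choosing a sequencing budget from a"
      "\ncurve like this rather than defaulting to maximal depth.")
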