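"""Normalize counts, select features, and thin reads.

Median-of-ratios size factors remove library-size differences; the
variance filter keeps the top 25% most variable genes (20477 genes would
give exactly 5120); binomial thinning emulates shallower sequencing.
"""

import numpy as np

from subtypecurves import (CohortConfig, deseq_size_factors, normalize_log2,
                           simulate_cohort, thin_counts, variance_filter)

cohort = simulate_cohort(CohortConfig(n_samples=60, n_genes=4000,
                                      n_informative=200, seed=2))
counts = cohort.counts

sf = deseq_size_factors(counts)
print("size factors span %.2f-%.2f (1.0 = the 'typical' library)"
      % (sf.min(), sf.max()))

expr = normalize_log2(counts, sf)
print("normalized expression: log2(count/sf + 1), range %.1f-%.1f"
      % (expr.to_numpy().min(), expr.to_numpy().max()))

top25 = variance_filter(expr, 0.25)
print("top-25%% variance filter: %d of %d genes kept (ceil rule)"
      % (top25.shape[0], expr.shape[0]))

target = int(counts.sum(axis=0).median() // 10)
thinned = thin_counts(counts, target, seed=0)
ratio = thinned.to_numpy().sum() / counts.to_numpy().sum()
print("thinning every sample to %d reads keeps %.0f%% of all counts —"
      % (target, 100 * ratio),
      "the read-depth experiments rerun the classifiers on such matrices")
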