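"""Unsupervised subtyping: cluster, prune, transfer labels, classify.

Hierarchical clustering (correlation distance, average linkage) is pruned
to significantly reproducible clusters with a SigClust-style Monte-Carlo
test; cluster centroids are matched to reference subtype centroids by
Spearman correlation in the priority order Basal, Normal, Her2, LumA, LumB.
"""

import pandas as pd

from subtypecurves import (CohortConfig, assign_subtype_labels,
                           cluster_centroids, hclust_corr_average,
                           informative_panel, normalize_counts,
                           prune_to_significant, simulate_cohort,
                           subset_panel)

cohort = simulate_cohort(CohortConfig(
    n_samples=300, n_genes=1500, n_informative=200,
    effect_size=2.5, lumAB_correlation=0.0, seed=6))
expr, _ = normalize_counts(cohort.counts)
panel, _ = subset_panel(expr, informative_panel(cohort, 40))

tree = hclust_corr_average(panel)
clusters = prune_to_significant(tree, panel, alpha=0.05, n_sim=100, seed=1)
print("significance pruning found", clusters.nunique(), "clusters")

centroids = cluster_centroids(panel, clusters)
reference = cohort.true_centroids.loc[panel.index]
mapping = assign_subtype_labels(centroids, reference)
print("cluster -> subtype:", {int(k): v for k, v in mapping.items()})

transferred = clusters.map(mapping)
agreement = (transferred == cohort.annotation["subtype"]).mean()
print("transferred labels agree with the hidden truth for %.0f%% of samples"
      % (100 * agreement))
print(pd.crosstab(cohort.annotation["subtype"], transferred))
print("\nWith well-separated centroids the five subtype clusters are"
      "\nrecovered without any labels; at realistic effect sizes the two"
      "\nluminal subtypes merge or bleed into each other, which is exactly"
      "\nwhere the supervised models keep their edge.")
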