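"""Cluster the selected genes by their fitted coefficient patterns.

k-means on each gene's (beta_mg, beta_mf, beta_ig, beta_if) vector groups
the selected genes into three pattern clusters; each cluster is tagged with
the canonical sign pattern it matches: cluster-1-like (+,-,+,-) both tissues
track insulin sensitivity, cluster-2-like (+,-,-,+) IMAT opposes muscle,
cluster-3-like (-,+,0,0) muscle-only inverse association.
"""

import pandas as pd

import imatnet as im
from imatnet.clustering import beta_features, summarize_cluster_patterns

cohort = im.generate_cohort(im.CohortSpec(seed=1))
muscle, imat, truth = im.generate_expression(cohort, im.GeneSpec(seed=2))
m, pheno = im.align(muscle, cohort)
i, _ = im.align(imat, cohort)
fits = im.fit_all_genes(m, i, pheno)
ranking = im.rank_and_select(fits, n_top=59)

selected_fits = [f for f in fits if f.gene_id in set(ranking.selected)]
features = beta_features(selected_fits)
scores = pd.Series({f.gene_id: f.score for f in selected_fits})
assignment = im.cluster_genes(features, k=3, scores=scores, seed=0)
summary = summarize_cluster_patterns(assignment, selected_fits)

print("cluster sizes:", assignment.sizes())
cols = ["cluster", "n_genes", "mean_beta_mg", "mean_beta_if", "pattern_tag"]
print(summary.table[cols].round(3).to_string(index=False))
# The tags recover the three planted templates. Recovered sizes track the
# 14/23/22 planting only approximately: clusters 1 and 2 share the muscle
# sign pattern and differ only in IMAT, so their boundary is the noisiest.
# Consensus columns (not shown) give the fraction of member genes agreeing
# with each majority sign.
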