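"""Per-gene joint regression of (GIR, FG) on (muscle, IMAT) expression.

Each gene gets a 2x2 coefficient matrix (beta_mg, beta_mf, beta_ig, beta_if)
estimated jointly, plus a likelihood-ratio score against the no-association
null. Ranking by score and keeping the top 59 recovers the planted genes.
"""

import imatnet as im
from imatnet.regression import fits_to_frame

cohort = im.generate_cohort(im.CohortSpec(seed=1))
muscle, imat, truth = im.generate_expression(cohort, im.GeneSpec(seed=2))

m, pheno = im.align(muscle, cohort)
i, _ = im.align(imat, cohort)
fits = im.fit_all_genes(m, i, pheno)
ranking = im.rank_and_select(fits, n_top=59)

frame = fits_to_frame(fits, ranking)
print(frame.head(5)[["gene_id", "beta_mg", "beta_mf", "beta_ig", "beta_if",
                     "score", "rank"]].round(3).to_string(index=False))

planted = set(truth.loc[truth["template"] != "null", "gene_id"])
hits = sum(g in planted for g in ranking.selected)
print(f"\nplanted genes among the selected top 59: {hits}/59")
# A high count means the likelihood score separates genuinely coupled genes
# from the 500 null genes at the cohort's sample size (n=16).
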