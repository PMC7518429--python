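"""Gene-ratio correlation screen and pre-ranked enrichment.

Screens every gene against the latent lipid/protein ratio with Spearman
correlation at the |rho| > 0.95 cutoff, then scores the planted positive
gene set with the weighted running-sum enrichment statistic.
"""

import warnings

from ramanmet import pearson_r_pvalue, preranked_enrichment, spearman_screen, synthetic

matrix, truth = synthetic.simulate_expression_matrix(seed=0)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pos, neg, table = spearman_screen(matrix, truth.extras["lipid_ratio"], cutoff=0.95)

planted_pos = {g for g, s in truth.planted_gene_sign.items() if s > 0}
planted_neg = {g for g, s in truth.planted_gene_sign.items() if s < 0}
print(f"screen: {len(pos)} genes with rho > 0.95, {len(neg)} with rho < -0.95")
print(f"planted positive genes recovered: {len(planted_pos & set(pos))}/{len(planted_pos)}")
print(f"planted negative genes recovered: {len(planted_neg & set(neg))}/{len(planted_neg)}")

ranked = table.sort_values("rho", ascending=False)
res = preranked_enrichment(
    list(ranked.index), ranked["rho"].to_numpy(), sorted(planted_pos), n_perm=1000, seed=0
)
print(f"pre-ranked enrichment of the planted set: ES = {res.ES:.3f}, p = {res.p_perm:.4f}")

print(f"p-value of a Pearson r = 0.93 over 5 cell lines: {pearson_r_pvalue(0.93, 5):.4f}")
print(
    "-> near-perfect monotone genes survive the 0.95 screen; the planted "
    "set piles up at the top of the ranking (ES near 1), and a 5-point "
    "r = 0.93 is significant at p ~ 0.02."
)
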