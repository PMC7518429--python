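"""Phenotype mapping of an expression matrix.

Projects a four-phenotype expression matrix onto the two dominant
deviation constraints, computes per-gene phenotype contribution scores
(S1..S4 from the G1/G2 loadings) and ranks phenotype-specific genes.
"""

from ramanmet import (
    cluster_rows,
    fit_surprisal,
    phenotype_contribution_scores,
    sample_projection_2d,
    synthetic,
    top_phenotype_genes,
)

matrix, truth = synthetic.simulate_expression_matrix(seed=0)
decomp = fit_surprisal(matrix)
coords, loadings = sample_projection_2d(decomp)

for pheno in ("melanocytic", "transitory", "neural-crest", "undifferentiated"):
    sel = [s for s in matrix.samples if truth.phenotype_label[s] == pheno]
    print(
        f"{pheno:>16}: mean 2-D position "
        f"({coords.loc[sel, 'x'].mean():+.2f}, {coords.loc[sel, 'y'].mean():+.2f})"
    )

scores = phenotype_contribution_scores(loadings)
top = top_phenotype_genes(scores, "melanocytic", n=5)
print("top melanocytic-score genes:", ", ".join(top))

order, _ = cluster_rows(matrix.values[:30])
print(f"average-linkage leaf order of the first 30 genes starts: {order[:8]} ...")
print(
    "-> the four phenotypes occupy distinct corners of the (lambda_1, "
    "lambda_2) map; contribution scores turn each gene's map loading into "
    "a per-phenotype ranking."
)
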