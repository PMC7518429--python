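"""Surprisal analysis of single-cell Raman spectra.

Generates C-H-region spectra for five cell-line-like groups whose lipid
fraction decreases along a differentiation axis, fits the steady-state +
constraints decomposition, and shows that the first deviation constraint
(lambda_1) is the lipid/protein axis.
"""

import numpy as np

from ramanmet import fit_surprisal, reconstruct, synthetic

matrix, truth = synthetic.simulate_spectra_matrix(
    n_groups=5, n_per_group=10, noise_sd=0.02, seed=0
)
decomp = fit_surprisal(matrix, pin_feature=2845.0)

rec = reconstruct(decomp, decomp.n_constraints)
print(f"full-rank reconstruction max |error|: {np.max(np.abs(rec - decomp.log_matrix)):.2e}")

f = np.array([truth.lipid_fraction[s] for s in matrix.samples])
corr = np.corrcoef(decomp.weight_of(1), f)[0, 1]
print(f"corr(lambda_1 weight, planted lipid fraction) = {corr:.4f}")

feats = np.asarray(matrix.features, dtype=float)
g = decomp.pattern_of(1)
g2845 = g[np.argmin(np.abs(feats - 2845))]
g2940 = g[np.argmin(np.abs(feats - 2940))]
print(f"lambda_1 loading at 2845 cm^-1 (CH2, lipid):   {g2845:+.4f}")
print(f"lambda_1 loading at 2940 cm^-1 (CH3, protein): {g2940:+.4f}")
print(
    "-> lambda_1 weighs lipid CH2 against protein CH3: a cell's lambda_1 "
    "score is its lipid/protein balance, and it tracks the planted "
    "differentiation ordering almost perfectly."
)
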