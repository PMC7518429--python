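"""Surprisal analysis of positive matrices.

The log-intensity matrix ln X_i(c) (feature i, sample c) is written as a
steady-state term plus deviation constraints,

    ln X_i(c) = sum_j G_ij * lambda_j(c),

where constraint 0 is the steady state shared by all samples, G_ij is the
sample-independent feature pattern of constraint j and lambda_j(c) its
sample-dependent weight.  The decomposition is fitted by a thin SVD of
ln X without centering: G holds the left singular vectors (orthonormal
columns) and lambda_j(c) the singular value times the right singular vector
entry, so the full-rank sum reproduces ln X exactly.

Also provides the 2-D phenotype projection onto the two dominant deviation
constraints, per-gene phenotype contribution scores for the four melanoma
de-differentiation states, top-n phenotype gene selection, and deterministic
average-linkage hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from ramanmet.spectra import SpectraMatrix, PSEUDOCOUNT_FRACTION

PHENOTYPES = ("melanocytic", "transitory", "neural-crest", "undifferentiated")

#: Score formulas mapping (G1, G2) loadings to the four phenotype scores.
_SCORE_SIGNS = {
    "melanocytic": (-1, -1),
    "transitory": (-1, +1),
    "neural-crest": (+1, +1),
    "undifferentiated": (+1, -1),
}


@dataclass
class SurprisalDecomposition:
    """Result of fitting the steady-state + constraints model by SVD."""

    features: list
    samples: list[str]
    G: np.ndarray  # feature x constraint, orthonormal columns
    weights: np.ndarray  # constraint x sample, lambda_j(c) incl. singular value
    singular_values: np.ndarray  # descending
    log_matrix: np.ndarray  # ln X actually fitted (after flooring)

    #: index of the steady-state constraint
    steady_state_index: int = 0

    @property
    def n_constraints(self) -> int:
        return self.G.shape[1]

    def weight_of(self, j: int) -> np.ndarray:
        """lambda_j(c) across samples."""
        return self.weights[j]

    def pattern_of(self, j: int) -> np.ndarray:
        """G_ij across features."""
        return self.G[:, j]


def _apply_sign_convention(G, weights, pin_feature_index=None):
    """Flip each constraint so its largest-|loading| feature is positive.

    ``pin_feature_index`` overrides the rule for constraint 1: that feature's
    loading is made positive (used to pin CH2 2845 cm^-1 positive so the
    lipid direction is 'up', matching the conventional orientation).
    """
    for j in range(G.shape[1]):
        if j == 1 and pin_feature_index is not None:
            ref = G[pin_feature_index, j]
        else:
            ref = G[np.argmax(np.abs(G[:, j])), j]
        if ref < 0:
            G[:, j] *= -1
            weights[j] *= -1
    return G, weights


def fit_surprisal(
    matrix: SpectraMatrix,
    n_constraints: int | None = None,
    pin_feature=None,
    pseudocount_fraction: float = PSEUDOCOUNT_FRACTION,
) -> SurprisalDecomposition:
    """Fit the surprisal decomposition of a strictly positive matrix.

    Parameters
    ----------
    matrix:
        Positive feature x sample matrix; entries below the pseudocount
        floor are raised to it before the log transform.
    n_constraints:
        Number of constraints to retain (including the steady state).
        ``None`` keeps the full thin-SVD rank.
    pin_feature:
        Optional feature id whose loading in constraint 1 is pinned
        positive (e.g. ``2845.0`` for Raman data).  By default each
        constraint is oriented so its largest-magnitude loading is positive.
    """
    floored = matrix.floor(pseudocount_fraction)
    L = np.log(floored.values)
    n_feat, n_samp = L.shape
    if n_samp < 2:
        warnings.warn("fewer than 2 samples: only the steady-state constraint is returned")
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    weights = s[:, None] * Vt
    pin_idx = None
    if pin_feature is not None:
        feats = np.asarray(matrix.features, dtype=float)
        pin_idx = int(np.argmin(np.abs(feats - float(pin_feature))))
    G, weights = _apply_sign_convention(U, weights, pin_idx)
    if n_samp < 2:
        n_constraints = 1
    if n_constraints is not None:
        if not 1 <= n_constraints <= G.shape[1]:
            raise ValueError(f"n_constraints must be in [1, {G.shape[1]}]")
        G = G[:, :n_constraints]
        weights = weights[:n_constraints]
        s = s[:n_constraints]
    return SurprisalDecomposition(
        features=list(matrix.features),
        samples=list(matrix.samples),
        G=G,
        weights=weights,
        singular_values=s,
        log_matrix=L,
    )


def reconstruct(decomp: SurprisalDecomposition, k: int) -> np.ndarray:
    """Sum of the first ``k`` constraints, sum_{j<k} G_ij * lambda_j(c) (log scale)."""
    if not 1 <= k <= decomp.n_constraints:
        raise ValueError(f"k must be in [1, {decomp.n_constraints}]")
    return decomp.G[:, :k] @ decomp.weights[:k]


def reconstruction_correlation(decomp: SurprisalDecomposition, k: int) -> float:
    """Pearson correlation between the k-constraint reconstruction and ln X."""
    rec = reconstruct(decomp, k).ravel()
    return float(pearsonr(rec, decomp.log_matrix.ravel())[0])


def sample_projection_2d(decomp: SurprisalDecomposition):
    """Project samples onto the two dominant deviation constraints.

    Returns ``(coords, loadings)``: per-sample (lambda_1, lambda_2)
    coordinates and per-feature (G1, G2) loadings, as DataFrames.  The
    steady state (constraint 0) is sample-invariant and excluded.
    """
    if decomp.n_constraints < 3:
        raise ValueError("projection requires at least 3 constraints (steady state + 2)")
    coords = pd.DataFrame(
        {"x": decomp.weights[1], "y": decomp.weights[2]}, index=decomp.samples
    )
    loadings = pd.DataFrame(
        {"G1": decomp.G[:, 1], "G2": decomp.G[:, 2]}, index=decomp.features
    )
    return coords, loadings


def phenotype_contribution_scores(loadings: pd.DataFrame) -> pd.DataFrame:
    """Phenotype contribution scores from 2-D map loadings.

    S_melanocytic = -G1 - G2, S_transitory = -G1 + G2,
    S_neural-crest = G1 + G2, S_undifferentiated = G1 - G2;
    hence S_melanocytic = -S_neural-crest and S_transitory =
    -S_undifferentiated, exactly.
    """
    G1 = np.asarray(loadings["G1"], dtype=float)
    G2 = np.asarray(loadings["G2"], dtype=float)
    if not (np.all(np.isfinite(G1)) and np.all(np.isfinite(G2))):
        raise ValueError("loadings must be finite")
    out = pd.DataFrame(index=loadings.index)
    out["G1"], out["G2"] = G1, G2
    for name, (a, b) in _SCORE_SIGNS.items():
        out[name] = a * G1 + b * G2
    return out


def top_phenotype_genes(
    scores: pd.DataFrame,
    phenotype: str,
    n: int = 100,
    restrict_to=None,
) -> list[str]:
    """Top-n features ranked by one phenotype's contribution score.

    Descending by score; ties broken by lexicographic feature id.
    ``restrict_to`` limits candidates (e.g. to a metabolic gene list).
    """
    if phenotype not in _SCORE_SIGNS:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    sub = scores
    if restrict_to is not None:
        allowed = set(restrict_to)
        sub = scores.loc[[g for g in scores.index if g in allowed]]
    if n > len(sub):
        raise ValueError(f"requested top {n} of only {len(sub)} candidates")
    ranked = sorted(sub.index, key=lambda g: (-sub.at[g, phenotype], str(g)))
    return list(ranked[:n])


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    # At each merge the subtree containing the smaller minimum original
    # index goes left; gives a platform-independent leaf order.
    min_idx = {i: i for i in range(n)}
    children = {}
    for m, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        if min_idx[a] > min_idx[b]:
            a, b = b, a
        children[n + m] = (a, b)
        min_idx[n + m] = min_idx[a]

    order: list[int] = []
    stack = [n + len(Z) - 1] if len(Z) else [0]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            a, b = children[node]
            stack.extend((b, a))
    return order


def cluster_rows(values: np.ndarray):
    """Average-linkage agglomerative clustering of rows (Euclidean distance).

    Returns ``(leaf_order, Z)`` with ``Z`` the SciPy linkage matrix and a
    deterministic leaf order (subtree with the smaller minimum original row
    index placed first at every merge).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("rows contain non-finite values")
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    return _leaf_order(Z, X.shape[0]), Z


def write_decomposition(decomp: SurprisalDecomposition, prefix, sep: str = "\t") -> None:
    """Serialize G, weights and singular values as three delimited tables."""
    cons = [f"constraint_{j}" for j in range(decomp.n_constraints)]
    pd.DataFrame(decomp.G, index=decomp.features, columns=cons).to_csv(
        f"{prefix}_patterns.tsv", sep=sep, index_label="feature"
    )
    pd.DataFrame(decomp.weights, index=cons, columns=decomp.samples).to_csv(
        f"{prefix}_weights.tsv", sep=sep, index_label="constraint"
    )
    pd.Series(decomp.singular_values, index=cons, name="singular_value").to_csv(
        f"{prefix}_singular_values.tsv", sep=sep, index_label="constraint"
    )
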