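import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ramanmet.spectra import SpectraMatrix
from ramanmet.surprisal import (
    cluster_rows,
    fit_surprisal,
    phenotype_contribution_scores,
    reconstruct,
    reconstruction_correlation,
    sample_projection_2d,
    top_phenotype_genes,
)


def make_matrix(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return SpectraMatrix(
        features=[f"{prefix}{i}" for i in range(values.shape[0])],
        samples=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestFit:
    def test_full_rank_reconstruction(self, toy_matrix):
        d = fit_surprisal(toy_matrix)
        rec = reconstruct(d, d.n_constraints)
        assert np.max(np.abs(rec - d.log_matrix)) < 1e-8

    def test_identical_columns_are_rank_one(self):
        col = np.array([1.0, 2.0, 5.0])
        m = make_matrix(np.column_stack([col] * 4))
        d = fit_surprisal(m)
        np.testing.assert_allclose(d.weights[1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(reconstruct(d, 1), d.log_matrix, atol=1e-12)

    def test_single_sample_steady_state_only(self):
        col = np.array([[2.0], [3.0], [4.0]])
        with pytest.warns(UserWarning, match="fewer than 2"):
            d = fit_surprisal(make_matrix(col))
        assert d.n_constraints == 1
        ln = np.log(col[:, 0])
        np.testing.assert_allclose(np.abs(d.G[:, 0]), np.abs(ln) / np.linalg.norm(ln), atol=1e-12)
        assert abs(d.weights[0, 0]) == pytest.approx(np.linalg.norm(ln))

    def test_orthonormal_patterns_and_descending_singular_values(self, toy_matrix):
        d = fit_surprisal(toy_matrix)
        np.testing.assert_allclose(d.G.T @ d.G, np.eye(d.n_constraints), atol=1e-12)
        assert np.all(np.diff(d.singular_values) <= 1e-12)

    def test_steady_state_weight_uniform_sign(self, raman_matrix):
        d = fit_surprisal(raman_matrix[0])
        signs = np.sign(d.weights[0])
        assert np.all(signs == signs[0])

    def test_truncation_matches_eigensolver_rank_k_optimum(self):
        # Eckart–Young: truncated-SVD residual equals the optimum computed
        # from an independent eigendecomposition of the Gram matrix L^T L
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 2.0, size=(6, 4))
        d = fit_surprisal(make_matrix(X))
        L = d.log_matrix
        err_svd = np.linalg.norm(L - reconstruct(d, 2))
        ev = np.sort(np.linalg.eigh(L.T @ L)[0])
        err_eig = np.sqrt(max(ev[: L.shape[1] - 2].sum(), 0.0))
        assert abs(err_svd - err_eig) < 1e-10

    def test_truncation_error_nonincreasing_in_k(self, toy_matrix):
        d = fit_surprisal(toy_matrix)
        errs = [
            np.linalg.norm(d.log_matrix - reconstruct(d, k))
            for k in range(1, d.n_constraints + 1)
        ]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_out_of_range_k_rejected(self, toy_matrix):
        d = fit_surprisal(toy_matrix)
        with pytest.raises(ValueError):
            reconstruct(d, 0)
        with pytest.raises(ValueError):
            reconstruct(d, d.n_constraints + 1)


class TestRamanRecovery:
    """Parameter recovery on the study-like synthetic spectra (criterion conditions)."""

    def test_lambda1_tracks_lipid_fraction(self, raman_matrix):
        matrix, truth = raman_matrix
        d = fit_surprisal(matrix, pin_feature=2845.0)
        f = np.array([truth.lipid_fraction[s] for s in matrix.samples])
        corr = np.corrcoef(d.weight_of(1), f)[0, 1]
        assert abs(corr) >= 0.95

    def test_lambda1_opposite_signs_at_ch2_ch3(self, raman_matrix):
        matrix, _ = raman_matrix
        d = fit_surprisal(matrix, pin_feature=2845.0)
        feats = np.asarray(matrix.features, dtype=float)
        g = d.pattern_of(1)
        i2845 = int(np.argmin(np.abs(feats - 2845)))
        i2940 = int(np.argmin(np.abs(feats - 2940)))
        assert g[i2845] > 0 and g[i2940] < 0

    def test_five_constraint_reconstruction_is_faithful(self):
        # low-noise conditions, as for spectra averaged over many acquisitions
        from ramanmet.synthetic import simulate_spectra_matrix

        matrix, _ = simulate_spectra_matrix(noise_sd=0.002, seed=0)
        d = fit_surprisal(matrix)
        assert reconstruction_correlation(d, 5) > 0.999


class TestProjection:
    def test_identical_columns_project_to_origin(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        m = make_matrix(np.column_stack([col] * 4))
        coords, _ = sample_projection_2d(fit_surprisal(m))
        np.testing.assert_allclose(coords.to_numpy(), 0.0, atol=1e-12)

    def test_duplicated_samples_coincide(self, toy_matrix):
        dup = SpectraMatrix(
            features=list(toy_matrix.features),
            samples=[f"{s}{tag}" for tag in ("", "_dup") for s in toy_matrix.samples],
            values=np.hstack([toy_matrix.values, toy_matrix.values]),
        )
        coords, _ = sample_projection_2d(fit_surprisal(dup))
        n = len(toy_matrix.samples)
        np.testing.assert_allclose(
            coords.to_numpy()[:n], coords.to_numpy()[n:], atol=1e-9
        )

    def test_phenotype_clusters_separate(self, expression):
        from sklearn.metrics import silhouette_score

        matrix, truth = expression
        coords, _ = sample_projection_2d(fit_surprisal(matrix))
        labels = [truth.phenotype_label[s] for s in matrix.samples]
        assert silhouette_score(coords[["x", "y"]].to_numpy(), labels) > 0.25

    def test_too_few_constraints_rejected(self):
        m = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        d = fit_surprisal(m)  # rank 2: steady state + 1
        with pytest.raises(ValueError):
            sample_projection_2d(d)


class TestContributionScores:
    def test_direct_substitution(self):
        scores = phenotype_contribution_scores(pd.DataFrame({"G1": [1.0], "G2": [0.0]}))
        row = scores.iloc[0]
        assert (
            row["melanocytic"],
            row["transitory"],
            row["neural-crest"],
            row["undifferentiated"],
        ) == (-1.0, -1.0, 1.0, 1.0)

    def test_origin_and_negative_diagonal(self):
        scores = phenotype_contribution_scores(
            pd.DataFrame({"G1": [0.0, -1.0], "G2": [0.0, -1.0]})
        )
        assert (scores.iloc[0][list(scores.columns[2:])] == 0).all()
        row = scores.iloc[1]
        assert (row["melanocytic"], row["transitory"]) == (2.0, 0.0)
        assert (row["neural-crest"], row["undifferentiated"]) == (-2.0, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        g1=st.floats(-1e6, 1e6, allow_nan=False),
        g2=st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_antisymmetry_identities_exact(self, g1, g2):
        s = phenotype_contribution_scores(pd.DataFrame({"G1": [g1], "G2": [g2]})).iloc[0]
        assert s["melanocytic"] == -s["neural-crest"]
        assert s["transitory"] == -s["undifferentiated"]


class TestTopGenes:
    @pytest.fixture
    def scores(self):
        return phenotype_contribution_scores(
            pd.DataFrame({"G1": [-3.0, -2.0, -1.0], "G2": [0.0, 0.0, 0.0]}, index=["a", "b", "c"])
        )

    def test_ranking(self, scores):
        assert top_phenotype_genes(scores, "melanocytic", n=2) == ["a", "b"]

    def test_restriction(self, scores):
        assert top_phenotype_genes(scores, "melanocytic", n=2, restrict_to=["b", "c"]) == ["b", "c"]

    def test_unknown_phenotype_rejected(self, scores):
        with pytest.raises(ValueError, match="phenotype"):
            top_phenotype_genes(scores, "mesenchymal-ish", n=1)

    def test_planted_markers_recovered(self, expression):
        matrix, truth = expression
        d = fit_surprisal(matrix)
        coords, loadings = sample_projection_2d(d)
        scores = phenotype_contribution_scores(loadings)
        # orientation of the fitted map is arbitrary: find which score
        # direction points at the melanocytic samples' corner
        mel = [s for s, p in truth.phenotype_label.items() if p == "melanocytic"]
        cx, cy = coords.loc[mel, "x"].mean(), coords.loc[mel, "y"].mean()
        directions = {
            "melanocytic": (-1, -1),
            "transitory": (-1, 1),
            "neural-crest": (1, 1),
            "undifferentiated": (1, -1),
        }
        pheno = max(directions, key=lambda p: directions[p][0] * cx + directions[p][1] * cy)
        top = set(top_phenotype_genes(scores, pheno, n=100))
        planted_pos = [g for g, s in truth.planted_gene_sign.items() if s > 0]
        recovered = len(top & set(planted_pos)) / len(planted_pos)
        assert recovered >= 0.9


class TestClustering:
    def test_identical_rows_merge_first(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 1.0]])
        order, Z = cluster_rows(X)
        assert set(Z[0, :2].astype(int)) == {0, 2}
        assert Z[0, 2] == 0.0

    def test_hand_computed_average_linkage(self):
        # points 0, 1, 10 on a line: merge (0,1) at d=1, then with 10 at
        # average distance (|10-0| + |10-1|)/2 = 9.5
        order, Z = cluster_rows(np.array([[0.0], [1.0], [10.0]]))
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(9.5)
        assert order == [0, 1, 2]

    def test_permutation_invariance_of_tree(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        _, Z1 = cluster_rows(X)
        _, Z2 = cluster_rows(X[perm])
        assert np.allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_nonfinite_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_rows(np.array([[1.0, np.nan], [0.0, 1.0]]))
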