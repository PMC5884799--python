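import numpy as np
import pandas as pd
import pytest

from consensusde.stratify import (
    assign_groups,
    build_feature_matrix,
    flag_outliers,
    run_pca,
)


def pca_oracle(X):
    """Eigendecomposition of the covariance matrix of the centered data."""
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


class TestFeatureMatrix:
    def test_shape_is_comparisons_by_gene_union(self, make_long):
        long = make_long(
            [
                ("g1", "c1", "non_treated", 1.0, 0.01, True),
                ("g2", "c1", "non_treated", -1.2, 0.01, True),
                ("g2", "c2", "non_treated", 2.0, 0.01, True),
                ("g3", "c2", "non_treated", 1.1, 0.01, True),
                ("g4", "c3", "treated", -1.5, 0.01, True),
                ("g5", "c3", "treated", 1.5, 0.01, True),
            ]
        )
        matrix = build_feature_matrix(long)
        assert matrix.shape == (3, 5)

    def test_missing_entries_filled_with_zero(self, make_long):
        long = make_long(
            [
                ("g1", "c1", "non_treated", 3.0, 0.01, True),
                ("g2", "c2", "non_treated", 1.0, 0.01, True),
            ]
        )
        matrix = build_feature_matrix(long)
        col = matrix["g1"]
        assert (col != 0).sum() == 1

    def test_fewer_than_two_comparisons_rejected(self, make_long):
        long = make_long([("g1", "c1", "non_treated", 1.0, 0.01, True)])
        with pytest.raises(ValueError, match="at least 2"):
            build_feature_matrix(long)


class TestRunPca:
    def test_rank_one_matrix_concentrates_variance(self):
        base = np.array([1.0, 2.0, -1.0, 0.5])
        X = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base))
        result = run_pca(X)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        result = run_pca(pd.DataFrame(X))
        vals, vecs = pca_oracle(X)
        k = result.loadings.shape[1]
        # explained variance matches eigenvalues
        total = vals.sum()
        np.testing.assert_allclose(
            result.explained_variance_ratio, vals[:k] / total, atol=1e-8
        )
        # loadings match eigenvectors up to sign
        for j in range(k):
            dot = abs(result.loadings.iloc[:, j] @ vecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_full_reconstruction_of_centered_matrix(self, rng):
        X = rng.normal(size=(5, 7))
        result = run_pca(pd.DataFrame(X))
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        centered = X - X.mean(axis=0)
        assert np.abs(recon - centered).max() < 1e-8

    def test_duplicating_a_row_keeps_loading_span(self, rng):
        # the span of all non-degenerate components is the direction space of
        # the rows, which a duplicated row cannot enlarge or rotate
        X = rng.normal(size=(4, 6))
        base = run_pca(pd.DataFrame(X))
        dup = run_pca(pd.DataFrame(np.vstack([X, X[-1]])))
        B = base.loadings.to_numpy()[:, base.explained_variance_ratio > 1e-12]
        D = dup.loadings.to_numpy()[:, dup.explained_variance_ratio > 1e-12]
        assert B.shape == D.shape
        np.testing.assert_allclose(B @ B.T, D @ D.T, atol=1e-8)

    def test_degenerate_matrix_rejected(self):
        X = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            run_pca(X)


class TestFlagOutliers:
    def _result(self, scores):
        from consensusde.stratify import PcaResult

        df = pd.DataFrame(
            scores, index=[f"c{i}" for i in range(len(scores))],
            columns=[f"PC{j + 1}" for j in range(len(scores[0]))],
        )
        return PcaResult(
            scores=df, loadings=pd.DataFrame(), explained_variance_ratio=np.array([1.0])
        )

    def test_single_extreme_comparison_flagged(self, rng):
        scores = [[float(x)] for x in rng.normal(0, 1, 10)]
        scores.append([50.0])
        result = self._result(scores)
        assert flag_outliers(result, k=3.0, n_components=1) == ["c10"]

    def test_identical_scores_skip_zero_mad_component(self):
        result = self._result([[1.0], [1.0], [1.0], [1.0]])
        assert flag_outliers(result, k=3.0, n_components=1) == []

    def test_invariant_to_row_order(self, rng):
        scores = [[float(x)] for x in np.r_[rng.normal(0, 1, 9), 40.0]]
        result = self._result(scores)
        shuffled = self._result(scores)
        shuffled.scores = shuffled.scores.sample(frac=1, random_state=1)
        assert flag_outliers(result) == flag_outliers(shuffled)

    def test_manual_override_always_flagged(self, rng):
        result = self._result([[float(x)] for x in rng.normal(0, 1, 6)])
        assert flag_outliers(result, manual=["c2"]) == ["c2"]

    def test_planted_aberrant_comparisons_flagged_in_simulation(self, rng):
        # 12 coherent comparisons share a common signature; 2 have it scrambled
        signature = rng.normal(0, 2, 40)
        rows = [signature + rng.normal(0, 0.3, 40) for _ in range(12)]
        rows += [rng.permutation(signature) for _ in range(2)]
        X = pd.DataFrame(rows, index=[f"c{i}" for i in range(14)])
        result = run_pca(X)
        flagged = flag_outliers(result, k=3.0, n_components=2)
        assert set(flagged) == {"c12", "c13"}


class TestAssignGroups:
    def test_partition_sizes(self):
        metadata = {f"h{i}": "non_treated" for i in range(13)}
        metadata.update({f"t{i}": "treated" for i in range(22)})
        plan = assign_groups(metadata, list(metadata))
        sizes = pd.Series(plan.assignment).value_counts()
        assert len(plan.retained) == 35
        assert sizes["non_treated"] == 13
        assert sizes["treated"] == 22

    def test_outlier_exclusion_propagates(self):
        metadata = {"a": "non_treated", "b": "treated", "c": "treated"}
        plan = assign_groups(metadata, ["a", "b"])
        assert "c" not in plan.assignment

    def test_unlabeled_comparison_rejected(self):
        with pytest.raises(ValueError, match="no design metadata"):
            assign_groups({"a": "non_treated"}, ["a", "zz"])
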