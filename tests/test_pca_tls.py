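import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from hairomics import (
    SpectralCountMatrix,
    pca,
    select_top_fraction,
    total_loading_scores,
    tsne_embed,
    tsne_group_significance,
    variance_explained_by_subset,
)
from hairomics.pca_tls import PCAResult, max_perplexity


def matrix_of(rows, subjects=None):
    ids = [f"P{i+1}" for i in range(len(rows))]
    subjects = subjects or [f"S{j+1}" for j in range(len(rows[0]))]
    return SpectralCountMatrix(pd.DataFrame(rows, index=ids, columns=subjects))


def fake_pca(loadings_rows, varprops, protein_ids=None):
    k = len(varprops)
    comp = [f"PC{i+1}" for i in range(k)]
    ids = protein_ids or [f"P{i+1}" for i in range(len(loadings_rows))]
    return PCAResult(
        scores=pd.DataFrame(np.zeros((2, k)), columns=comp),
        loadings=pd.DataFrame(loadings_rows, index=ids, columns=comp),
        variance_proportions=pd.Series(varprops, index=comp),
    )


class TestPCA:
    def test_collinear_data_is_rank_one(self):
        # subjects lie on a line in 2-protein space
        m = matrix_of([[0, 2, 4, 6], [0, 1, 2, 3]])
        res = pca(m, log_transform=False)
        assert res.variance_proportions.iloc[0] == pytest.approx(1.0)
        assert res.variance_proportions.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_identity(self, small_cohort):
        matrix, _ = small_cohort
        res = pca(matrix)
        x = np.log1p(matrix.counts.T.to_numpy(dtype=float))
        centered = x - x.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_variance_proportions_match_eigendecomposition(self):
        rng = np.random.default_rng(0)
        m = matrix_of(rng.integers(0, 30, size=(3, 4)).tolist())
        res = pca(m, log_transform=False)
        x = m.counts.T.to_numpy(dtype=float)
        cov = np.cov(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig[: len(res.variance_proportions)] / eig.sum()
        np.testing.assert_allclose(
            res.variance_proportions.to_numpy(), expected, atol=1e-10
        )

    def test_proportions_sum_to_one(self, small_cohort):
        matrix, _ = small_cohort
        res = pca(matrix)
        assert res.variance_proportions.sum() == pytest.approx(1.0)

    def test_sign_convention(self, small_cohort):
        matrix, _ = small_cohort
        res = pca(matrix)
        for pc in res.loadings.columns:
            col = res.loadings[pc]
            assert col.iloc[np.argmax(col.abs().to_numpy())] > 0

    def test_constant_matrix_raises(self):
        m = matrix_of([[5, 5, 5], [2, 2, 2]])
        with pytest.raises(ValueError, match="no variance"):
            pca(m, log_transform=False)


class TestTotalLoadingScores:
    def test_worked_example(self):
        res = fake_pca([[0.5, -0.2, 0.1, 0.0, 0.0]], [0.4, 0.2, 0.1, 0.05, 0.05])
        table = total_loading_scores(res, n_pcs=5)
        assert table["tls"].iloc[0] == pytest.approx(0.25)

    def test_signed_mode_allows_cancellation(self):
        res = fake_pca([[0.5, -0.2, 0.1, 0.0, 0.0]], [0.4, 0.2, 0.1, 0.05, 0.05])
        table = total_loading_scores(res, n_pcs=5, magnitude=False)
        assert table["tls"].iloc[0] == pytest.approx(0.2 - 0.04 + 0.01)

    def test_zero_loadings_give_zero(self):
        res = fake_pca([[0.0] * 5, [0.3, 0, 0, 0, 0]], [0.4, 0.2, 0.1, 0.05, 0.05])
        table = total_loading_scores(res, n_pcs=5)
        assert table.loc["P1", "tls"] == 0.0

    def test_homogeneous_in_variance_proportions(self):
        rng = np.random.default_rng(1)
        loadings = rng.normal(size=(6, 5)).tolist()
        props = [0.3, 0.2, 0.1, 0.05, 0.05]
        t1 = total_loading_scores(fake_pca(loadings, props), n_pcs=5)
        t2 = total_loading_scores(fake_pca(loadings, [2 * p for p in props]), n_pcs=5)
        np.testing.assert_allclose(t2["tls"], 2 * t1["tls"])

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            loadings = rng.normal(size=(20, 6))
            props = rng.dirichlet(np.ones(6))
            res = fake_pca(loadings.tolist(), props.tolist())
            table = total_loading_scores(res, n_pcs=5)
            for i, pid in enumerate(res.loadings.index):
                expected = 0.0
                for k in range(5):
                    expected += abs(loadings[i, k]) * props[k]
                assert table.at[pid, "tls"] == expected

    def test_too_many_pcs_raises(self):
        res = fake_pca([[0.1, 0.2]], [0.6, 0.4])
        with pytest.raises(ValueError, match="exceeds"):
            total_loading_scores(res, n_pcs=5)


class TestSelectTopFraction:
    def table_of(self, tls_values, ids=None):
        ids = ids or [f"P{i+1}" for i in range(len(tls_values))]
        return pd.DataFrame({"tls": tls_values}, index=ids)

    def test_ceil_of_fraction(self):
        table = self.table_of(list(np.linspace(1, 0, 40)))
        assert len(select_top_fraction(table, 0.05)) == 2  # ceil(2.0)

    def test_fraction_one_selects_all(self):
        table = self.table_of([3.0, 1.0, 2.0])
        assert sorted(select_top_fraction(table, 1.0)) == ["P1", "P2", "P3"]

    def test_tie_broken_by_protein_id(self):
        table = self.table_of([0.5, 0.5, 0.1], ids=["PB", "PA", "PC"])
        assert select_top_fraction(table, 1 / 3) == ["PA"]

    def test_invalid_fraction(self):
        table = self.table_of([1.0])
        with pytest.raises(ValueError, match="top_fraction"):
            select_top_fraction(table, 0.0)
        with pytest.raises(ValueError, match="top_fraction"):
            select_top_fraction(table, 1.5)

    def test_is_top_count_matches(self, small_cohort):
        from hairomics import pca as run_pca

        matrix, _ = small_cohort
        table = total_loading_scores(run_pca(matrix), top_fraction=0.05)
        assert table["is_top"].sum() == int(np.ceil(0.05 * matrix.n_proteins))
        assert set(select_top_fraction(table, 0.05)) == set(table.index[table["is_top"]])


class TestVarianceExplained:
    def test_full_set_explains_everything(self, small_cohort):
        matrix, _ = small_cohort
        assert variance_explained_by_subset(matrix, matrix.protein_ids) == pytest.approx(100.0)

    def test_three_to_one_variance_split(self):
        # per-protein variances 3 and 1 -> first protein carries 75%
        m = matrix_of([[0, 3, 3], [0, 1, 2]])
        assert variance_explained_by_subset(m, ["P1"], log_transform=False) == pytest.approx(75.0)

    def test_empty_subset_warns_zero(self, small_cohort):
        matrix, _ = small_cohort
        with pytest.warns(UserWarning, match="empty subset"):
            assert variance_explained_by_subset(matrix, []) == 0.0

    def test_zero_variance_subset(self):
        m = matrix_of([[2, 2, 2], [0, 1, 2]])
        assert variance_explained_by_subset(m, ["P1"], log_transform=False) == 0.0


def blob_matrix(rng, n_per_blob=10, separation=60):
    a = rng.poisson(5, size=(5, n_per_blob))
    b = rng.poisson(5 + separation, size=(5, n_per_blob))
    counts = np.hstack([a, b])
    subjects = [f"A{i}" for i in range(n_per_blob)] + [f"B{i}" for i in range(n_per_blob)]
    return matrix_of(counts.tolist(), subjects=subjects)


class TestTsne:
    def test_shapes_and_determinism(self):
        m = blob_matrix(np.random.default_rng(0))
        e1 = tsne_embed(m, seed=7, n_repeats=2, max_iter=260)
        e2 = tsne_embed(m, seed=7, n_repeats=2, max_iter=260)
        assert len(e1) == 2
        for a, b in zip(e1, e2):
            assert a.shape == (20, 2)
            pd.testing.assert_frame_equal(a, b)
        assert not e1[0].equals(e1[1])  # distinct repeat seeds

    def test_max_perplexity_rule(self):
        assert max_perplexity(40) == 13
        assert max_perplexity(4) == 1

    def test_too_few_subjects(self):
        m = matrix_of([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError, match="at least 4 subjects"):
            tsne_embed(m, seed=0)

    def test_separated_blobs_stay_separated(self):
        m = blob_matrix(np.random.default_rng(1))
        labels = [s[0] for s in m.subject_ids]
        for emb in tsne_embed(m, seed=0, n_repeats=3, max_iter=300):
            assert silhouette_score(emb.to_numpy(), labels) > 0.3

    def test_significance_perfect_separation(self):
        m = blob_matrix(np.random.default_rng(2))
        labels = [s[0] for s in m.subject_ids]
        res = tsne_group_significance(
            m, labels, n_permutations=49, seed=0, max_iter=300
        )
        assert res.empirical_p == pytest.approx(1 / 50)

    def test_invariant_statistic_gives_p_one(self):
        m = blob_matrix(np.random.default_rng(3))
        labels = [s[0] for s in m.subject_ids]
        res = tsne_group_significance(
            m, labels, statistic=lambda e, lab: 1.0, n_permutations=20, seed=0, max_iter=260
        )
        assert res.empirical_p == 1.0

    def test_single_group_rejected(self):
        m = blob_matrix(np.random.default_rng(4))
        with pytest.raises(ValueError, match="2 distinct groups"):
            tsne_group_significance(m, ["x"] * 20, n_permutations=5, seed=0)
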