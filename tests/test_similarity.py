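import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hairomics import (
    SpectralCountMatrix,
    euclidean_distance_matrix,
    generate_cohort,
    hierarchical_clustering,
    manhattan_distance,
    spearman_matrix,
)
from hairomics.similarity import DistanceMatrix
from hairomics.simulate import CohortSpec


def matrix_of(columns: dict) -> SpectralCountMatrix:
    counts = pd.DataFrame(columns)
    counts.index = [f"P{i+1}" for i in range(len(counts))]
    return SpectralCountMatrix(counts)


class TestSpearman:
    def test_self_correlation_is_one(self):
        m = matrix_of({"S1": [1, 5, 2], "S2": [4, 4, 9]})
        rho = spearman_matrix(m)
        assert np.allclose(np.diag(rho), 1.0)

    def test_rank_difference_formula_example(self):
        # d^2 = (0,1,1,0) -> rho = 1 - 6*2/(4*15) = 0.8
        m = matrix_of({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        assert spearman_matrix(m).at["x", "y"] == pytest.approx(0.8)

    def test_reversed_ranks_give_minus_one(self):
        m = matrix_of({"x": [1, 2, 3, 4], "y": [9, 7, 4, 2]})
        assert spearman_matrix(m).at["x", "y"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, small_cohort):
        matrix, _ = small_cohort
        squared = SpectralCountMatrix(matrix.counts**2, matrix.structural)
        pd.testing.assert_frame_equal(spearman_matrix(matrix), spearman_matrix(squared))

    def test_zero_variance_subject_is_nan_with_warning(self):
        m = matrix_of({"S1": [1, 2, 3], "S2": [5, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            rho = spearman_matrix(m)
        assert np.isnan(rho.at["S1", "S2"])
        assert rho.at["S1", "S1"] == 1.0


class TestEuclidean:
    def test_identical_columns_zero(self):
        m = matrix_of({"S1": [3, 1], "S2": [3, 1]})
        assert euclidean_distance_matrix(m, log_transform=False).values.at["S1", "S2"] == 0

    def test_three_four_five_triangle(self):
        m = matrix_of({"S1": [0, 0], "S2": [3, 4]})
        d = euclidean_distance_matrix(m, log_transform=False)
        assert d.values.at["S1", "S2"] == pytest.approx(5.0)

    def test_log_transform_changes_scale(self):
        m = matrix_of({"S1": [0, 0], "S2": [3, 4]})
        d = euclidean_distance_matrix(m, log_transform=True)
        expected = np.hypot(np.log1p(3), np.log1p(4))
        assert d.values.at["S1", "S2"] == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(arrays(np.int64, (4, 3), elements=st.integers(0, 50)))
    def test_metric_axioms(self, data):
        counts = pd.DataFrame(data, index=list("abcd"), columns=["x", "y", "z"])
        d = euclidean_distance_matrix(SpectralCountMatrix(counts)).values.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestManhattan:
    def test_single_flip(self):
        assert manhattan_distance([1, 0, 1], [0, 0, 1]) == 1

    def test_identical_profiles(self):
        assert manhattan_distance([1, 1, 0], [1, 1, 0]) == 0

    def test_maximal_case(self):
        assert manhattan_distance([1] * 7, [0] * 7) == 7

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            manhattan_distance([1, 0], [1])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        arrays(np.int8, 12, elements=st.integers(0, 1)),
        arrays(np.int8, 12, elements=st.integers(0, 1)),
        arrays(np.int8, 12, elements=st.integers(0, 1)),
    )
    def test_metric_axioms_on_binary(self, a, b, c):
        assert manhattan_distance(a, b) == manhattan_distance(b, a)
        assert manhattan_distance(a, a) == 0
        assert manhattan_distance(a, c) <= manhattan_distance(a, b) + manhattan_distance(b, c)


class TestHierarchicalClustering:
    def make_distance(self):
        values = pd.DataFrame(
            [[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        return DistanceMatrix(values, "euclidean")

    def test_nearest_pair_merges_first(self):
        dend = hierarchical_clustering(self.make_distance())
        a, b, height = dend.merges[0]
        assert {a, b} == {0, 1}
        assert height == pytest.approx(1.0)

    def test_n_minus_one_merges(self, small_cohort):
        matrix, _ = small_cohort
        dend = hierarchical_clustering(euclidean_distance_matrix(matrix))
        assert len(dend.merges) == matrix.n_subjects - 1

    def test_unknown_linkage_lists_supported(self):
        with pytest.raises(ValueError, match="single.*complete.*average.*ward"):
            hierarchical_clustering(self.make_distance(), "median")

    def test_deterministic_across_runs(self, small_cohort):
        matrix, _ = small_cohort
        d = euclidean_distance_matrix(matrix)
        assert hierarchical_clustering(d).merges == hierarchical_clustering(d).merges

    def test_cut_recovers_obvious_split(self):
        dend = hierarchical_clustering(self.make_distance())
        labels = dend.cut(2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_newick_parses_and_keeps_leaves(self, small_cohort):
        from Bio import Phylo

        matrix, _ = small_cohort
        dend = hierarchical_clustering(euclidean_distance_matrix(matrix))
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(matrix.subject_ids)

    def test_mothers_cluster_with_strong_depth_effect(self):
        """With a 3x maternal depth multiplier, cutting the log-count
        dendrogram at k=2 isolates at least 7 of 8 mothers in most seeds."""
        successes = 0
        for seed in range(12):
            spec = CohortSpec(
                n_proteins=200, n_age_proteins=10, n_sex_proteins=5,
                mother_depth_multiplier=3.0, seed=seed,
            )
            matrix, meta = generate_cohort(spec)
            dend = hierarchical_clustering(euclidean_distance_matrix(matrix))
            labels = dend.cut(2)
            best = max(
                sum(labels[m] == c for m in meta.mothers) for c in labels.unique()
            )
            successes += best >= 7
        assert successes >= 8
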