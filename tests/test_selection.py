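"""Correlation, MDS embedding and the four selection strategies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from refselect.selection import (
    CorrelationMatrix,
    SelectionError,
    correlation_matrix,
    mds_embed,
    select_all,
    select_knn,
    select_kmeans,
    select_random,
)

from conftest import make_matrix
from oracles import knn_brute, pearson_brute


class TestCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        m = make_matrix([[10, 10], [20, 20], [30, 30]])
        corr = correlation_matrix(m)
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_reversed_profiles_anticorrelate(self):
        m = make_matrix([[1, 3], [2, 2], [3, 1]])
        corr = correlation_matrix(m)
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, toy_matrix):
        corr = correlation_matrix(toy_matrix)
        X = toy_matrix.counts
        for i in range(3):
            for j in range(3):
                expected = pearson_brute(list(X[:, i]), list(X[:, j]))
                assert corr.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, toy_matrix):
        corr = correlation_matrix(toy_matrix)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_zero_variance_sample_named(self):
        m = make_matrix([[5, 1], [5, 2], [5, 3]], samples=["FLAT", "OK"])
        with pytest.raises(SelectionError, match="FLAT"):
            correlation_matrix(m)

    def test_needs_two_targets(self):
        with pytest.raises(SelectionError, match="2 targets"):
            correlation_matrix(make_matrix([[1, 2]]))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 500, size=(rng.integers(3, 12), rng.integers(2, 8)))
        m = make_matrix(counts.astype(float))
        try:
            corr = correlation_matrix(m)
        except SelectionError:
            return  # a zero-variance column was drawn
        for i in range(m.n_samples):
            for j in range(m.n_samples):
                expected = pearson_brute(list(counts[:, i]), list(counts[:, j]))
                assert corr.values[i, j] == pytest.approx(expected, abs=1e-9)


class TestMDS:
    def _corr_from_dist(self, D):
        return CorrelationMatrix(
            samples=[f"S{i}" for i in range(len(D))], values=1.0 - np.asarray(D)
        )

    def test_equidistant_triplet_stays_equidistant(self):
        D = 0.4 * (1 - np.eye(3))
        emb = mds_embed(self._corr_from_dist(D), m=2)
        d = pdist(emb.coordinates)
        assert np.ptp(d) < 1e-9

    def test_coordinates_centered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        emb = mds_embed(self._corr_from_dist(D), m=4)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_euclidean_distances_recovered_at_full_rank(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        emb = mds_embed(self._corr_from_dist(D), m=5)
        np.testing.assert_allclose(
            squareform(pdist(emb.coordinates)), D, atol=1e-8
        )

    def test_truncation_warns_when_rank_deficient(self):
        # 3 collinear points: only 1 positive eigenvalue
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="truncating"):
            emb = mds_embed(self._corr_from_dist(D), m=2)
        assert emb.coordinates.shape[1] == 1

    def test_two_batches_split_on_first_axis(self):
        from refselect.depthio import apply_qc
        from refselect.simcohort import SimConfig, simulate

        matrix, truth = simulate(
            SimConfig(n_samples=30, n_batches=2, capture_sd=0.5, seed=21)
        )
        matrix, _ = apply_qc(matrix)
        emb = mds_embed(correlation_matrix(matrix), m=2)
        labels = truth.batch_labels(matrix.samples)
        axis0 = emb.coordinates[:, 0]
        # a single threshold on the first coordinate separates the batches
        assert max(axis0[labels == 0]) < min(axis0[labels == 1]) or max(
            axis0[labels == 1]
        ) < min(axis0[labels == 0])


class TestSelectAll:
    def test_definition(self):
        m = make_matrix(np.ones((2, 3)) * [[1, 2, 3], [4, 5, 6]], samples=list("ABC"))
        a = select_all(m)
        assert a.references == {"A": ["B", "C"], "B": ["A", "C"], "C": ["A", "B"]}

    def test_list_lengths(self, study_cohort):
        matrix, _ = study_cohort
        a = select_all(matrix)
        assert all(len(v) == matrix.n_samples - 1 for v in a.references.values())


class TestSelectRandom:
    def test_exhaustive_size_equals_all(self, toy_matrix):
        a = select_random(toy_matrix, size=2, seed=3)
        assert a.reference_sets() == select_all(toy_matrix).reference_sets()

    def test_seed_determinism(self, study_cohort):
        matrix, _ = study_cohort
        a = select_random(matrix, size=10, seed=42)
        b = select_random(matrix, size=10, seed=42)
        c = select_random(matrix, size=10, seed=43)
        assert a.references == b.references
        assert a.references != c.references

    def test_size_out_of_range(self, toy_matrix):
        with pytest.raises(SelectionError):
            select_random(toy_matrix, size=3, seed=0)
        with pytest.raises(SelectionError):
            select_random(toy_matrix, size=0, seed=0)

    def test_draw_is_uniform(self):
        """With S=11, size=1, a fixed query picks each other sample ~1/10."""
        rng = np.random.default_rng(5)
        counts = rng.integers(50, 200, size=(5, 11)).astype(float)
        m = make_matrix(counts)
        query = m.samples[0]
        freq = {s: 0 for s in m.samples if s != query}
        n_draws = 10_000
        for seed in range(n_draws):
            a = select_random(m, size=1, seed=seed)
            freq[a.references[query][0]] += 1
        for s, c in freq.items():
            assert c / n_draws == pytest.approx(0.1, abs=0.01)


class TestSelectKnn:
    def _corr(self, values, samples):
        return CorrelationMatrix(samples=samples, values=np.asarray(values, float))

    def test_top_k_matches_row_sort(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            S = int(rng.integers(3, 12))
            A = rng.uniform(-1, 1, size=(S, S))
            values = np.clip((A + A.T) / 2, -1, 1)
            np.fill_diagonal(values, 1.0)
            samples = [f"S{i:02d}" for i in range(S)]
            corr = self._corr(values, samples)
            for k in (1, S // 2 + 1, S - 1):
                a = select_knn(corr, k=k)
                for i, s in enumerate(samples):
                    assert a.references[s] == knn_brute(values, samples, i, k)

    def test_tie_broken_by_ascending_id(self):
        values = np.array(
            [[1.0, 0.5, 0.5, 0.2],
             [0.5, 1.0, 0.1, 0.3],
             [0.5, 0.1, 1.0, 0.3],
             [0.2, 0.3, 0.3, 1.0]]
        )
        corr = self._corr(values, ["A", "B", "C", "D"])
        a = select_knn(corr, k=1)
        assert a.references["A"] == ["B"]  # B and C tie at 0.5; B < C

    def test_k_equals_s_minus_one_is_all(self, toy_matrix):
        corr = correlation_matrix(toy_matrix)
        knn = select_knn(corr, k=2).reference_sets()
        assert knn == select_all(toy_matrix).reference_sets()

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        S = 7
        A = rng.uniform(-1, 1, size=(S, S))
        values = np.clip((A + A.T) / 2, -1, 1)
        np.fill_diagonal(values, 1.0)
        corr = self._corr(values, [f"S{i}" for i in range(S)])
        prev = None
        for k in range(1, S):
            cur = select_knn(corr, k=k).reference_sets()
            if prev is not None:
                assert all(prev[s] <= cur[s] for s in cur)
            prev = cur

    def test_batch_purity(self, batch_cohort):
        """Below the batch size, neighbours always come from the same batch."""
        matrix, truth = batch_cohort
        corr = correlation_matrix(matrix)
        a = select_knn(corr, k=10)
        for s in matrix.samples:
            batches = {truth.batch_of[r] for r in a.references[s]}
            assert batches == {truth.batch_of[s]}


class TestSelectKmeans:
    def test_k1_equals_all(self, toy_matrix):
        a = select_kmeans(toy_matrix, k=1, seed=0)
        assert a.reference_sets() == select_all(toy_matrix).reference_sets()
        assert set(a.labels.values()) == {0}

    def test_recovers_batches(self, batch_cohort):
        matrix, truth = batch_cohort
        a = select_kmeans(matrix, k=4, seed=1)
        ari = adjusted_rand_score(
            truth.batch_labels(matrix.samples),
            [a.labels[s] for s in matrix.samples],
        )
        assert ari == 1.0

    def test_cluster_members_share_reference_sets(self, batch_cohort):
        matrix, truth = batch_cohort
        a = select_kmeans(matrix, k=4, seed=1)
        for s in matrix.samples:
            full = set(a.references[s]) | {s}
            peers = [t for t in matrix.samples if a.labels[t] == a.labels[s]]
            assert full == set(peers)

    def test_k_equals_s_gives_empty_sets_with_warning(self, toy_matrix):
        with pytest.warns(UserWarning, match="singleton"):
            a = select_kmeans(toy_matrix, k=3, seed=0)
        assert all(v == [] for v in a.references.values())

    def test_determinism(self, batch_cohort):
        matrix, _ = batch_cohort
        a = select_kmeans(matrix, k=4, seed=9)
        b = select_kmeans(matrix, k=4, seed=9)
        assert a.labels == b.labels and a.references == b.references


@given(seed=st.integers(0, 10_000), method=st.sampled_from(["all", "random", "knn", "kmeans"]))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_no_method_self_references(seed, method):
    rng = np.random.default_rng(seed)
    counts = rng.integers(20, 400, size=(6, 8)).astype(float)
    m = make_matrix(counts)
    if method == "all":
        a = select_all(m)
    elif method == "random":
        a = select_random(m, size=3, seed=seed)
    elif method == "knn":
        a = select_knn(correlation_matrix(m), k=3)
    else:
        a = select_kmeans(m, k=2, seed=seed)
    for s, refs in a.references.items():
        assert s not in refs
        assert set(refs) <= set(m.samples)


class TestMedianScaledCorrelation:
    def test_scaled_values_match_direct_computation(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 400, size=(15, 5)).astype(float)
        m = make_matrix(counts)
        scaled = correlation_matrix(m, median_scale=True)
        manual = counts / np.median(counts, axis=1)[:, None]
        for i in range(5):
            for j in range(5):
                expected = pearson_brute(list(manual[:, i]), list(manual[:, j]))
                assert scaled.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_scaling_damps_a_dominant_target(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(80, 120, size=(20, 4)).astype(float)
        counts[0, :] = [10_000, 10_050, 9_900, 10_100]  # one huge target
        m = make_matrix(counts)
        raw = correlation_matrix(m)
        scaled = correlation_matrix(m, median_scale=True)
        # the dominant target inflates raw correlations toward 1
        off = ~np.eye(4, dtype=bool)
        assert raw.values[off].mean() > 0.99
        assert scaled.values[off].mean() < raw.values[off].mean() - 0.5

    def test_nonpositive_median_target_rejected(self):
        counts = np.full((5, 2), 100.0)
        counts[2, :] = 0.0
        m = make_matrix(counts)
        with pytest.raises(SelectionError, match="median"):
            correlation_matrix(m, median_scale=True)
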