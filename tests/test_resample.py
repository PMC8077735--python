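import numpy as np
import pytest

from carbsite import resample
from carbsite.features import FeatureMatrix
from carbsite.resample import (
    KSUConfig,
    SMOTEConfig,
    compute_plan,
    ksu_dissimilarity,
    ksu_undersample,
    round_half_away_from_zero,
    smote,
    smote_ksu,
)


class TestComputePlan:
    @pytest.mark.parametrize(
        "n1,n0,expected_N",
        [(618, 26995, 13189), (162, 22418, 11128), (204, 22849, 11323), (191, 24271, 12040)],
    )
    def test_published_training_counts(self, n1, n0, expected_N):
        plan = compute_plan(n1, n0)
        assert plan.N == expected_N
        assert plan.M == n1 + expected_N
        assert plan.additions + n1 == plan.M
        assert n0 - plan.removals == plan.M

    def test_k_site_balanced_size(self):
        assert compute_plan(618, 26995).M == 13807

    def test_half_integer_rounds_away_from_zero(self):
        # 0.5*(22849 - 204) = 11322.5 must round up, not to even
        assert compute_plan(204, 22849).N == 11323
        assert round_half_away_from_zero(-2.5) == -3

    @pytest.mark.parametrize("n1,n0", [(10, 10), (11, 10), (0, 5)])
    def test_degenerate_counts_rejected(self, n1, n0):
        with pytest.raises(ValueError, match="balanced or inverted"):
            compute_plan(n1, n0)


class TestSmote:
    def test_zero_additions_gives_empty(self):
        out = smote(np.zeros((3, 2)), 0, SMOTEConfig(k_neighbors=1))
        assert out.shape == (0, 2)

    def test_two_point_interpolant_on_the_segment(self):
        out = smote(np.array([[0.0, 0.0], [1.0, 1.0]]), 1, SMOTEConfig(k_neighbors=1, seed=5))
        [row] = out
        assert row[0] == pytest.approx(row[1])  # on the diagonal segment
        assert 0.0 < row[0] < 1.0

    def test_quota_larger_than_minority_size(self, rng):
        X = rng.normal(size=(8, 4))
        out = smote(X, 25, SMOTEConfig(k_neighbors=3, seed=0))
        assert out.shape == (25, 4)

    def test_rows_interpolate_base_and_true_neighbor(self, rng):
        X = rng.normal(size=(30, 6))
        cfg = SMOTEConfig(k_neighbors=5, seed=2)
        out, prov, u = smote(X, 40, cfg, return_provenance=True)
        # brute-force neighbour lists as the oracle
        d = np.linalg.norm(X[:, None] - X[None], axis=2)
        np.fill_diagonal(d, np.inf)
        for row, (base, nb), ui in zip(out, prov, u):
            assert nb in np.argsort(d[base])[:5]
            np.testing.assert_allclose(row, X[base] + ui * (X[nb] - X[base]))
            assert 0.0 < ui < 1.0

    def test_synthetics_stay_in_minority_bounding_box(self, rng):
        X = rng.uniform(-3, 7, size=(12, 5))
        out = smote(X, 100, SMOTEConfig(seed=1))
        assert np.all(out >= X.min(axis=0) - 1e-12)
        assert np.all(out <= X.max(axis=0) + 1e-12)

    def test_minority_smaller_than_k_errors(self):
        with pytest.raises(ValueError, match="minority"):
            smote(np.zeros((4, 2)), 3, SMOTEConfig(k_neighbors=5))

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(10, 3))
        a = smote(X, 12, SMOTEConfig(seed=7))
        b = smote(X, 12, SMOTEConfig(seed=7))
        assert np.array_equal(a, b)


class TestKsuDissimilarity:
    def test_hand_computed_pair(self):
        pairs = ksu_dissimilarity(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert pairs == [(0, 1, pytest.approx(1.0))]  # (1/2)(1+1)

    def test_identical_rows_have_zero_distance(self):
        pairs = ksu_dissimilarity(np.array([[2.0, 3.0], [2.0, 3.0]]))
        assert pairs[0][2] == 0.0

    def test_column_normalized_by_maximum(self):
        # column (2, 4) -> (0.5, 1.0); other column constant-zero stays zero
        pairs = ksu_dissimilarity(np.array([[2.0, 0.0], [4.0, 0.0]]))
        assert pairs[0][2] == pytest.approx(0.25 / 2)

    def test_single_row_cluster_yields_no_pairs(self):
        assert ksu_dissimilarity(np.array([[1.0, 2.0]])) == []

    def test_against_naive_full_matrix(self, rng):
        A = rng.uniform(0, 5, size=(20, 7))
        n = A.shape[0]
        col_max = A.max(axis=0)
        pi = np.where(col_max != 0, A / np.where(col_max == 0, 1, col_max), 0.0)
        D = np.zeros((n, n))
        for p in range(n):
            for q in range(n):
                diff = pi[p] - pi[q]
                D[p, q] = diff @ diff / n
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        for p, q, d1 in ksu_dissimilarity(A):
            assert p < q
            assert d1 == pytest.approx(D[p, q])


class TestKsuUndersample:
    def test_zero_removals_is_identity(self, rng):
        X = rng.normal(size=(10, 3))
        assert np.array_equal(ksu_undersample(X, 0, KSUConfig(n_clusters=2)), X)

    def test_duplicates_removed_first(self, rng):
        X = rng.normal(size=(6, 3))
        X[4] = X[1]  # exact duplicate pair -> dissimilarity 0, ranked first
        kept, alive = ksu_undersample(X, 1, KSUConfig(n_clusters=1, seed=0), return_mask=True)
        assert kept.shape == (5, 3)
        assert not (alive[1] and alive[4])

    def test_survivors_are_original_rows_in_order(self, rng):
        X = rng.normal(size=(40, 4))
        kept = ksu_undersample(X, 15, KSUConfig(n_clusters=3, seed=1))
        assert kept.shape == (25, 4)
        rows = {tuple(r) for r in X}
        positions = [np.flatnonzero((X == r).all(axis=1))[0] for r in kept]
        assert all(tuple(r) in rows for r in kept)
        assert positions == sorted(positions)

    def test_fallback_when_pairs_exhausted(self, caplog):
        # 3 singleton-ish clusters of 1 row each can rank no pairs
        X = np.array([[0.0], [100.0], [200.0], [300.0]])
        kept = ksu_undersample(X, 3, KSUConfig(n_clusters=4, seed=0))
        assert kept.shape == (1, 1)

    def test_removals_must_leave_a_survivor(self):
        with pytest.raises(ValueError, match="cannot remove"):
            ksu_undersample(np.zeros((5, 2)), 5, KSUConfig())


class TestSmoteKsu:
    @staticmethod
    def _matrix(n1, n0, dim, seed):
        rng = np.random.default_rng(seed)
        values = np.vstack([rng.normal(1, 1, (n1, dim)), rng.normal(0, 1, (n0, dim))])
        labels = np.r_[np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]
        return FeatureMatrix(values, labels, [f"f{i}" for i in range(dim)])

    def test_balances_both_classes_to_m(self):
        fm = self._matrix(20, 120, 6, seed=0)
        plan = compute_plan(20, 120)
        out = smote_ksu(fm, plan, SMOTEConfig(seed=1), KSUConfig(seed=2))
        assert out.class_counts() == (plan.M, plan.M)
        assert out.n_samples == 2 * plan.M
        assert out.synthetic.sum() == plan.additions
        # synthetic flags sit only on positive rows
        assert np.all(out.labels[out.synthetic] == 1)

    def test_plan_for_other_counts_rejected(self):
        fm = self._matrix(20, 120, 4, seed=3)
        with pytest.raises(ValueError, match="plan was computed"):
            smote_ksu(fm, compute_plan(10, 100))

    def test_balanced_input_errors(self):
        fm = self._matrix(30, 30, 4, seed=4)
        with pytest.raises(ValueError, match="balanced or inverted"):
            smote_ksu(fm)

    def test_identical_seeds_identical_output(self):
        fm = self._matrix(15, 90, 5, seed=6)
        a = smote_ksu(fm, None, SMOTEConfig(seed=9), KSUConfig(seed=10))
        b = smote_ksu(fm, None, SMOTEConfig(seed=9), KSUConfig(seed=10))
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.labels, b.labels)
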