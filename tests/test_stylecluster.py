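"""Two-step clustering: CF statistics, distances, agglomeration, k-selection
and predictor importance, checked against brute-force raw-point oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinstyle import stylecluster as sc
from kinstyle.errors import InsufficientDataError, InvalidArgumentError


# ---------------------------------------------------------------------------
# raw-point oracle: same quantities computed directly from point sets


def xi_raw(points, gvar):
    pts = np.atleast_2d(points)
    var = pts.var(axis=0) if pts.shape[0] > 1 else np.zeros(pts.shape[1])
    return -pts.shape[0] * 0.5 * np.sum(np.log(var + gvar))


def distance_raw(points_a, points_b, gvar):
    merged = np.vstack([np.atleast_2d(points_a), np.atleast_2d(points_b)])
    return max(xi_raw(points_a, gvar) + xi_raw(points_b, gvar)
               - xi_raw(merged, gvar), 0.0)


class TestCFEntry:
    def test_merge_adds_componentwise(self, rng):
        a = sc.CFEntry.from_points(rng.standard_normal((4, 3)))
        b = sc.CFEntry.from_points(rng.standard_normal((7, 3)))
        m = a.merge(b)
        assert m.N == 11
        assert np.allclose(m.LS, a.LS + b.LS)
        assert np.allclose(m.SS, a.SS + b.SS)

    def test_variance_matches_numpy(self, rng):
        pts = rng.standard_normal((20, 5))
        e = sc.CFEntry.from_points(pts)
        assert np.allclose(e.variances(), pts.var(axis=0), atol=1e-10)

    def test_singleton_variance_zero(self):
        e = sc.CFEntry.from_points(np.array([1.0, -2.0, 3.0]))
        assert np.allclose(e.variances(), 0.0)


class TestLoglikDistance:
    def test_identical_singletons_distance_zero(self):
        p = np.array([0.3, -1.2])
        a = sc.CFEntry.from_points(p)
        b = sc.CFEntry.from_points(p)
        assert sc.loglik_distance(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = sc.CFEntry.from_points(rng.standard_normal((3, 4)))
            b = sc.CFEntry.from_points(rng.standard_normal((5, 4)))
            assert sc.loglik_distance(a, b) == pytest.approx(
                sc.loglik_distance(b, a), rel=1e-12)

    def test_cf_equals_raw_point_computation(self, rng):
        """CF statistics are a sufficient summary: the distance computed
        from (N, LS, SS) equals the distance computed from raw points."""
        gvar = 1.0
        for _ in range(100):
            na, nb = rng.integers(1, 6, 2)
            d = int(rng.integers(1, 6))
            A = rng.standard_normal((na, d)) * rng.uniform(0.5, 3)
            B = rng.standard_normal((nb, d)) + rng.uniform(-2, 2)
            got = sc.loglik_distance(sc.CFEntry.from_points(A),
                                     sc.CFEntry.from_points(B), gvar)
            assert got == pytest.approx(distance_raw(A, B, gvar), abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        a = sc.CFEntry.from_points(rng.standard_normal((2, 3)))
        b = sc.CFEntry.from_points(rng.standard_normal((2, 4)))
        with pytest.raises(InvalidArgumentError):
            sc.loglik_distance(a, b)


class TestPrecluster:
    def test_zero_threshold_gives_singletons(self, rng):
        X = rng.standard_normal((12, 3))
        entries, assign = sc.precluster(X, distance_threshold=0.0)
        assert len(entries) == 12
        assert sorted(assign.tolist()) == list(range(12))

    def test_infinite_threshold_gives_one_entry(self, rng):
        X = rng.standard_normal((15, 4))
        entries, assign = sc.precluster(X, distance_threshold=np.inf)
        assert len(entries) == 1
        assert entries[0].N == 15
        assert np.allclose(entries[0].LS, X.sum(axis=0))
        assert np.allclose(entries[0].SS, (X ** 2).sum(axis=0))

    def test_counts_conserved_and_pure_on_blobs(self, rng):
        blob1 = rng.standard_normal((30, 2)) * 0.2
        blob2 = rng.standard_normal((30, 2)) * 0.2 + 8.0
        X = np.vstack([blob1, blob2])
        order = rng.permutation(60)
        entries, assign = sc.precluster(X[order], distance_threshold=2.0)
        assert sum(e.N for e in entries) == 60
        truth = (order >= 30).astype(int)
        for j in range(len(entries)):
            members = truth[assign == j]
            assert len(set(members.tolist())) == 1  # purity

    def test_rebuild_caps_entry_count(self, rng):
        X = rng.standard_normal((40, 2))
        entries, assign = sc.precluster(X, distance_threshold=0.0,
                                        max_subclusters=10)
        assert len(entries) <= 10
        assert sum(e.N for e in entries) == 40
        assert assign.max() < len(entries)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sc.precluster(np.empty((0, 3)))


class TestAgglomerate:
    def test_k_equals_m_is_identity(self, rng):
        X = rng.standard_normal((8, 2))
        entries = [sc.CFEntry.from_points(x) for x in X]
        labels, _ = sc.agglomerate(entries, 8)
        assert len(set(labels.tolist())) == 8

    def test_k_one_single_cluster(self, rng):
        X = rng.standard_normal((6, 2))
        entries = [sc.CFEntry.from_points(x) for x in X]
        labels, _ = sc.agglomerate(entries, 1)
        assert set(labels.tolist()) == {0}

    def test_three_blobs_recovered(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.standard_normal((20, 2)) * 0.3 + c
                       for c in centers])
        entries = [sc.CFEntry.from_points(x) for x in X]
        labels, _ = sc.agglomerate(entries, 3)
        truth = np.repeat([0, 1, 2], 20)
        assert pd.crosstab(truth, labels).to_numpy().max(axis=1).sum() == 60

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """On <= 8 points, the merge sequence must equal the brute-force
        best-merge sequence computed from raw point sets."""
        gvar = 1.0
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.standard_normal((n, 3))
            history = sc.agglomerate_full(
                [sc.CFEntry.from_points(x) for x in X], gvar)
            # oracle: greedy merging of raw point-index sets
            sets = [{i} for i in range(n)]
            oracle = {n: [frozenset(s) for s in sets]}
            while len(sets) > 1:
                best, bi, bj = np.inf, -1, -1
                for i in range(len(sets)):
                    for j in range(i + 1, len(sets)):
                        d = distance_raw(X[sorted(sets[i])],
                                         X[sorted(sets[j])], gvar)
                        if d < best - 1e-12:
                            best, bi, bj = d, i, j
                sets[bi] = sets[bi] | sets[bj]
                del sets[bj]
                oracle[len(sets)] = [frozenset(s) for s in sets]
            for k, parts in oracle.items():
                labels = history.labels_at[k]
                got = [frozenset(np.flatnonzero(labels == c).tolist())
                       for c in range(k)]
                assert set(got) == set(parts)

    def test_invalid_k_rejected(self, rng):
        entries = [sc.CFEntry.from_points(x)
                   for x in rng.standard_normal((4, 2))]
        with pytest.raises(InvalidArgumentError):
            sc.agglomerate(entries, 0)
        with pytest.raises(InvalidArgumentError):
            sc.agglomerate(entries, 5)


class TestSelectK:
    def _fit_gaussians(self, rng, centers, n_per, scale=1.0):
        X = np.vstack([rng.standard_normal((n_per, centers.shape[1])) * scale
                       + c for c in centers])
        return sc.fit_two_step(X)

    def test_single_gaussian_k1_modal(self):
        ks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            model = self._fit_gaussians(rng, np.zeros((1, 5)), 60)
            ks.append(model.k)
        counts = pd.Series(ks).value_counts()
        assert counts.idxmax() == 1

    def test_three_separated_blobs_k3(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0, 0], [8, 0, 0], [0, 8, 8]], float)
        model = self._fit_gaussians(rng, centers, 40)
        assert model.k == 3

    def test_kmax_returned_when_no_plateau(self):
        # strictly improving BIC with flat merge-distance ratios
        bic = -np.arange(10, dtype=float) * 100.0
        dist = {k: 2.0 ** k for k in range(2, 11)}
        with pytest.warns(UserWarning):
            k = sc.select_k(bic, dist)
        assert k == 10

    def test_increasing_bic_gives_one(self):
        bic = np.arange(5, dtype=float)
        assert sc.select_k(bic, {k: 1.0 for k in range(2, 6)}) == 1


class TestPredictorImportance:
    def test_best_predictor_scores_one(self, rng):
        labels = np.repeat([1, 2], 30)
        X = rng.standard_normal((60, 5))
        X[:, 2] += labels * 3.0  # strongly separating column
        pi = sc.predictor_importance(X, labels)
        assert pi.iloc[2] == pytest.approx(1.0)
        assert pi.idxmax() == "x2"

    def test_formula_half_case(self):
        # -log10(0.01) = 2 against a best of 4 gives exactly 0.5
        out = sc.pi_from_significance(np.array([1e-4, 0.01]))
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(0.5)

    def test_pvalue_floor(self):
        out = sc.pi_from_significance(np.array([0.0, 0.5]))
        assert np.isfinite(out).all() and out[0] == 1.0

    def test_matches_scipy_f_oneway(self, rng):
        labels = np.repeat([1, 2, 3], 15)
        X = rng.standard_normal((45, 4))
        X[:, 0] += labels * 0.8
        pi = sc.predictor_importance(X, labels)
        pv = np.array([stats.f_oneway(*(X[labels == g, j] for g in (1, 2, 3)))[1]
                       for j in range(4)])
        assert np.allclose(pi.to_numpy(), sc.pi_from_significance(pv))

    def test_small_cluster_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(InsufficientDataError):
            sc.predictor_importance(X, np.array([1, 1, 1, 1, 2]))


class TestFitTwoStep:
    def test_labels_ordered_by_size(self, rng):
        X = np.vstack([rng.standard_normal((50, 2)) * 0.3,
                       rng.standard_normal((20, 2)) * 0.3 + 10])
        model = sc.fit_two_step(X, k=2)
        counts = np.bincount(model.assignments)[1:]
        assert counts[0] >= counts[1]
        assert model.shares().sum() == pytest.approx(100.0)

    def test_order_permutation_invariant_partition(self, rng):
        X = np.vstack([rng.standard_normal((30, 3)) * 0.3,
                       rng.standard_normal((30, 3)) * 0.3 + 8])
        m1 = sc.fit_two_step(X, k=2)
        perm = rng.permutation(60)
        m2 = sc.fit_two_step(X[perm], k=2)
        assert (m1.assignments[perm] == m2.assignments).all()

    def test_duplicated_trials_same_partition(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) * 0.4,
                       rng.standard_normal((20, 2)) * 0.4 + 9])
        m1 = sc.fit_two_step(X, k=2)
        m2 = sc.fit_two_step(np.vstack([X, X]), k=2)
        assert (m2.assignments[:40] == m2.assignments[40:]).all()
        assert (m1.assignments == m2.assignments[:40]).all()

    def test_kmax_lowered_with_warning(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.warns(UserWarning, match="k_max lowered"):
            sc.fit_two_step(X, k_max=15, k=1)

    def test_conservation_across_subclusters(self, pour_features):
        model = sc.fit_two_step(pour_features)
        assert sum(e.N for e in model.subclusters) == pour_features.n_trials

    def test_importances_in_unit_interval(self, pour_features):
        model = sc.fit_two_step(pour_features)
        assert model.k >= 2
        pi = model.importances
        assert ((pi >= 0) & (pi <= 1)).all()
        assert pi.max() == pytest.approx(1.0)
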