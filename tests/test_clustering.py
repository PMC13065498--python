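"""PAM clustering, diagnostics and the movement-type label mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from windforay import clustering as clu


def brute_force_kmedoids(X, k):
    D = cdist(np.atleast_2d(X.T).T if X.ndim == 1 else X,
              np.atleast_2d(X.T).T if X.ndim == 1 else X)
    return min(D[list(c)].min(axis=0).sum()
               for c in itertools.combinations(range(len(D)), k))


class TestPam:
    def test_worked_example(self):
        res = clu.pam(np.array([0.0, 1.0, 10.0, 11.0]), 2)
        assert res.cost == pytest.approx(2.0)
        assert list(res.assignment) == [0, 0, 1, 1]

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 11))
            k = int(rng.integers(1, min(4, n)))
            X = rng.normal(0, 1, (n, int(rng.integers(1, 4))))
            assert clu.pam(X, k).cost == pytest.approx(
                brute_force_kmedoids(X, k), abs=1e-9)

    def test_k_equals_n_minus_one(self):
        X = np.array([0.0, 1.0, 10.0, 11.0])
        res = clu.pam(X, 3)
        sizes = np.bincount(res.assignment)
        assert sorted(sizes) == [1, 1, 2]
        assert res.cost == pytest.approx(1.0)

    def test_guards(self):
        X = np.arange(4.0)
        with pytest.raises(ValueError):
            clu.pam(X, 4)
        with pytest.raises(ValueError):
            clu.pam(X, 0)
        with pytest.raises(ValueError):
            clu.pam(X[:1], 1)

    def test_duplicate_rows_allowed(self):
        X = np.array([0.0, 0.0, 5.0, 5.0])
        res = clu.pam(X, 2)
        assert res.cost == pytest.approx(0.0)

    def test_row_order_invariance_up_to_relabeling(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(5, 0.3, (25, 3))])
        perm = rng.permutation(len(X))
        a = clu.pam(X, 2)
        b = clu.pam(X[perm], 2)
        assert a.cost == pytest.approx(b.cost)
        sets_a = frozenset(frozenset(np.flatnonzero(a.assignment == c)) for c in range(2))
        sets_b = frozenset(frozenset(perm[np.flatnonzero(b.assignment == c)])
                           for c in range(2))
        assert sets_a == sets_b


class TestSilhouette:
    def test_worked_example_value(self):
        X = np.array([0.0, 1.0, 10.0, 11.0])
        res = clu.pam(X, 2)
        s = clu.silhouette(X, res.assignment)
        # a(0)=1, b(0)=(10+11)/2=10.5 -> s = 1 - 1/10.5
        assert s[0] == pytest.approx(1.0 - 1.0 / 10.5)
        assert res.silhouette_mean == pytest.approx(s.mean())

    def test_identical_pairs_perfect_cohesion(self):
        X = np.array([0.0, 0.0, 9.0, 9.0])
        s = clu.silhouette(X, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(s, 1.0)

    def test_equidistant_point_scores_zero(self):
        X = np.array([0.0, 2.0, 4.0, 6.0])
        s = clu.silhouette(X, np.array([0, 0, 1, 1]))
        # point 1: a=2, b=(2+4)/2=3 -> s>0; engineered case instead:
        X = np.array([0.0, 1.0, 2.0])
        s = clu.silhouette(X, np.array([0, 0, 1]))
        # middle point: a=1, b=1 -> 0
        assert s[1] == pytest.approx(0.0)

    def test_singleton_cluster_scores_zero(self):
        X = np.array([0.0, 1.0, 9.0])
        s = clu.silhouette(X, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            clu.silhouette(np.arange(4.0), np.zeros(4, dtype=int))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import silhouette_samples

        X = rng.normal(0, 1, (40, 3))
        res = clu.pam(X, 3)
        mine = clu.silhouette(X, res.assignment)
        ref = silhouette_samples(X, res.assignment)
        np.testing.assert_allclose(mine, ref, atol=1e-9)


class TestDiagnostics:
    def test_elbow_cost_non_increasing(self, rng):
        X = rng.normal(0, 1, (40, 3))
        curve = clu.elbow_curve(X, range(1, 8))
        assert (np.diff(curve["cost"]) <= 1e-9).all()

    def test_k1_cost_is_global_medoid_cost(self, rng):
        X = rng.normal(0, 1, (30, 2))
        D = cdist(X, X)
        assert clu.pam(X, 1).cost == pytest.approx(D.sum(axis=1).min())

    def test_gap_selects_two_for_separated_blobs(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = np.vstack([r.normal(0, 0.1, (50, 2)), r.normal(10, 0.1, (50, 2))])
            g = clu.gap_statistic(X, range(1, 5), B=20, seed=seed)
            hits += clu.select_k_gap(g) == 2
        assert hits >= 18  # ~ >= 45/50 rate at reduced repetitions

    def test_gap_prefers_one_for_uniform_blob(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.uniform(0, 1, (80, 2))
            g = clu.gap_statistic(X, range(1, 5), B=20, seed=seed)
            hits += clu.select_k_gap(g) == 1
        assert hits >= 6

    def test_gap_curve_finite(self, rng):
        X = rng.normal(0, 1, (40, 2))
        g = clu.gap_statistic(X, range(1, 6), B=10, seed=0)
        assert np.isfinite(g[["gap", "gap_se", "log_w"]].to_numpy()).all()

    def test_gap_b_guard(self, rng):
        with pytest.raises(ValueError):
            clu.gap_statistic(rng.normal(0, 1, (20, 2)), range(1, 3), B=5)


def _track_table(durations, dmax, direction=0.0):
    n = len(durations)
    return pd.DataFrame(
        {
            "track_id": np.arange(n),
            "complete": True,
            "metric_complete": True,
            "median_step_km": np.linspace(5, 6, n),
            "max_distance_km": dmax,
            "duration_h": durations,
            "straightness": 0.5,
            "median_direction_deg": direction,
        }
    )


class TestMovementLabels:
    def test_longer_duration_cluster_is_lrm(self, rng):
        durations = np.r_[rng.normal(4, 0.5, 30), rng.normal(30, 2, 10)]
        dmax = np.r_[rng.normal(10, 1, 30), rng.normal(120, 5, 10)]
        tracks = _track_table(durations, dmax)
        fm = clu.build_features(tracks)
        res = clu.pam(fm, 2)
        mapping = clu.assign_movement_labels(res, tracks, fm)
        labelled = clu.apply_cluster_labels(tracks, fm, res, mapping)
        med = labelled.groupby("label")["duration_h"].median()
        assert med["LRM"] > med["MRM"]
        assert (labelled["label"] != "").all()

    def test_duration_tie_breaks_on_distance(self):
        tracks = _track_table(np.r_[np.full(6, 5.0), np.full(6, 5.0)],
                              np.r_[np.full(6, 10.0), np.full(6, 80.0)])
        fm = clu.build_features(tracks)
        res = clu.pam(fm, 2)
        mapping = clu.assign_movement_labels(res, tracks, fm)
        labelled = clu.apply_cluster_labels(tracks, fm, res, mapping)
        assert (labelled.loc[labelled["max_distance_km"] > 40, "label"] == "LRM").all()

    def test_mapping_invariant_to_cluster_index_swap(self, rng):
        durations = np.r_[rng.normal(4, 0.5, 20), rng.normal(30, 2, 8)]
        dmax = np.r_[rng.normal(10, 1, 20), rng.normal(120, 5, 8)]
        tracks = _track_table(durations, dmax)
        fm = clu.build_features(tracks)
        res = clu.pam(fm, 2)
        mapping = clu.assign_movement_labels(res, tracks, fm)
        swapped = clu.PamResult(k=2, medoids=res.medoids[::-1].copy(),
                                assignment=1 - res.assignment, cost=res.cost,
                                iterations=res.iterations)
        mapping2 = clu.assign_movement_labels(swapped, tracks, fm)
        for c in (0, 1):
            assert mapping[c] == mapping2[1 - c]

    def test_k3_warns_and_keeps_single_lrm(self, rng):
        durations = np.r_[rng.normal(2, 0.2, 10), rng.normal(6, 0.2, 10),
                          rng.normal(30, 1, 10)]
        dmax = np.r_[rng.normal(5, 1, 10), rng.normal(20, 1, 10),
                     rng.normal(120, 5, 10)]
        tracks = _track_table(durations, dmax)
        fm = clu.build_features(tracks)
        res = clu.pam(fm, 3)
        with pytest.warns(UserWarning):
            mapping = clu.assign_movement_labels(res, tracks, fm)
        assert sorted(mapping.values())[-1] == "MRM2" or "LRM" in mapping.values()
        assert sum(v == "LRM" for v in mapping.values()) == 1


class TestFeatureMatrix:
    def test_z_columns_standardised(self, rng):
        tracks = _track_table(rng.gamma(4, 1, 40), rng.gamma(10, 2, 40),
                              direction=rng.uniform(0, 360, 40))
        tracks["straightness"] = rng.uniform(0.1, 1.0, 40)
        fm = clu.build_features(tracks)
        np.testing.assert_allclose(fm.values[:, :4].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(fm.values[:, :4].std(axis=0), 1.0, atol=1e-9)
        norms = np.hypot(fm.values[:, 4], fm.values[:, 5])
        np.testing.assert_allclose(norms, 1.0 / np.sqrt(2.0), atol=1e-12)

    def test_raw_feature_scaling_leaves_assignment_unchanged(self, rng):
        durations = np.r_[rng.normal(4, 0.5, 20), rng.normal(30, 2, 8)]
        dmax = np.r_[rng.normal(10, 1, 20), rng.normal(120, 5, 8)]
        tracks = _track_table(durations, dmax)
        fm1 = clu.build_features(tracks)
        scaled = tracks.copy()
        scaled["max_distance_km"] *= 10.0
        fm2 = clu.build_features(scaled)
        a = clu.pam(fm1, 2).assignment
        b = clu.pam(fm2, 2).assignment
        assert (a == b).all() or (a == 1 - b).all()

    def test_incomplete_tracks_excluded(self):
        tracks = _track_table(np.arange(1.0, 7.0), np.arange(10.0, 70.0, 10.0))
        tracks.loc[0, "complete"] = False
        tracks.loc[1, "metric_complete"] = False
        fm = clu.build_features(tracks)
        assert len(fm.values) == 4
        assert 0 not in fm.track_ids and 1 not in fm.track_ids
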