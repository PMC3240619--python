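import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineagetrack as lt
from lineagetrack.tracking import (
    DEFAULT_THRESHOLDS,
    TransitionMatrix,
    links_from_tracks,
    total_assigned_score,
)


def obs_row(cell_id, x, y, frame=0, **features):
    base = {
        "frame": frame, "cell_id": cell_id, "x": x, "y": y,
        "area": 100.0, "mean_hoechst": 50.0, "std_hoechst": 5.0,
        "moment2_area_norm": 900.0,
    }
    base.update(features)
    return base


def frame_df(rows):
    return pd.DataFrame(rows)


class TestMovementScore:
    def test_zero_difference_scores_exactly_one(self):
        assert lt.feature_movement_score(0.0, 3.0, 2.0) == 1.0

    def test_score_at_threshold_with_alphaT_five(self):
        # closed form: (1 + e^-5) / 2
        expected = (1 + np.exp(-5)) / 2
        assert lt.feature_movement_score(1.0, 1.0, 5.0) == pytest.approx(expected)

    def test_strictly_decreasing_and_vanishing(self):
        T, alpha = 4.0, 5.0 / 4.0
        d = np.linspace(0, 40, 200)
        s = lt.feature_movement_score(d, T, alpha)
        assert np.all(np.diff(s) < 0)
        assert s[-1] < 1e-3  # s(10T) << 1 for alpha*T = 5

    def test_negative_difference_uses_absolute_value(self):
        assert lt.feature_movement_score(-2.0, 3.0, 1.0) == lt.feature_movement_score(
            2.0, 3.0, 1.0
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lt.feature_movement_score(1.0, 0.0, 1.0)


class TestCombinedScore:
    def test_identical_observations_score_exactly_one(self):
        rng = np.random.default_rng(0)
        p = lt.TrackingParameters()
        for _ in range(100):
            a = obs_row(
                1, rng.uniform(0, 500), rng.uniform(0, 500),
                area=rng.uniform(50, 300), mean_hoechst=rng.uniform(20, 200),
                std_hoechst=rng.uniform(1, 20),
                moment2_area_norm=rng.uniform(100, 5000),
            )
            assert lt.combined_score(a, dict(a), p) == 1.0

    def test_literal_product_of_default_weights(self):
        p = lt.TrackingParameters(combine_mode="literal_product")
        a = obs_row(1, 10.0, 20.0)
        # identical pair: product of the weights 0.9 * 0.9 * 0.5^3
        assert lt.combined_score(a, dict(a), p) == pytest.approx(0.10125)

    def test_large_distance_drives_score_to_zero(self):
        p = lt.TrackingParameters()
        a = obs_row(1, 0.0, 0.0)
        b = obs_row(2, 10 * p.thresholds["distance"], 0.0)
        assert lt.combined_score(a, b, p) < 1e-3

    def test_missing_feature_skipped_with_warning(self):
        p = lt.TrackingParameters()
        a = obs_row(1, 0.0, 0.0)
        b = obs_row(2, 1.0, 0.0)
        b["std_hoechst"] = np.nan
        with pytest.warns(UserWarning):
            s = lt.combined_score(a, b, p)
        assert 0 < s <= 1


class TestTransitionMatrix:
    def test_single_pair_within_gate(self):
        p = lt.TrackingParameters()
        m = lt.build_transition_matrix(
            frame_df([obs_row(1, 10, 10)]), frame_df([obs_row(5, 12, 10, frame=1)]), p
        )
        assert set(m.scores) == {(1, 5)}
        assert 0 < m.scores[(1, 5)] <= 1

    def test_pairs_beyond_gate_absent(self):
        p = lt.TrackingParameters(distance_gate=15.0)
        m = lt.build_transition_matrix(
            frame_df([obs_row(1, 0, 0)]), frame_df([obs_row(2, 100, 100, frame=1)]), p
        )
        assert m.scores == {}

    def test_empty_frame_gives_empty_matrix(self):
        p = lt.TrackingParameters()
        m = lt.build_transition_matrix(frame_df([]), frame_df([obs_row(1, 0, 0)]), p)
        assert m.scores == {}

    def test_best_target_is_argmax_not_nearest(self):
        # two candidate targets: the nearer one has very different intensity,
        # the farther one matches; features override pure distance
        p = lt.TrackingParameters()
        src = obs_row(1, 0.0, 0.0, mean_hoechst=100.0, area=150.0)
        near = obs_row(10, 3.0, 0.0, frame=1, mean_hoechst=400.0, area=60.0,
                       std_hoechst=25.0, moment2_area_norm=4000.0)
        far = obs_row(11, 8.0, 0.0, frame=1, mean_hoechst=101.0, area=150.0)
        m = lt.build_transition_matrix(frame_df([src]), frame_df([near, far]), p)
        assert m.scores[(1, 11)] > m.scores[(1, 10)]


class TestEstimateThresholds:
    def test_constant_differences_give_that_constant(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(50, 450, size=(60, 2))
        rows_t = [obs_row(i, x, y) for i, (x, y) in enumerate(pts)]
        rows_t1 = [obs_row(i, x + 3.0, y, frame=1) for i, (x, y) in enumerate(pts)]
        thresholds, gate = lt.estimate_thresholds(
            [frame_df(rows_t), frame_df(rows_t1)], percentile=95
        )
        assert thresholds["distance"] == pytest.approx(3.0)
        assert gate >= thresholds["distance"]

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError):
            lt.estimate_thresholds([], percentile=100)

    def test_too_few_links_falls_back_to_defaults(self):
        with pytest.warns(UserWarning):
            thresholds, _ = lt.estimate_thresholds(
                [frame_df([obs_row(1, 10, 10)]), frame_df([obs_row(1, 11, 10, frame=1)])]
            )
        assert thresholds == DEFAULT_THRESHOLDS


def dense_matrix(M, dists=None):
    n, m = M.shape
    rows, cols = list(range(n)), list(range(100, 100 + m))
    return TransitionMatrix(
        rows, cols,
        {(i, 100 + j): float(M[i, j]) for i in range(n) for j in range(m)},
        {(i, 100 + j): float(dists[i, j]) if dists is not None else 0.0
         for i in range(n) for j in range(m)},
    )


def brute_force_best(M):
    n, m = M.shape
    best = 0.0
    if n <= m:
        for cols in itertools.permutations(range(m), n):
            best = max(best, sum(M[i, c] for i, c in enumerate(cols)))
    else:
        for rows in itertools.permutations(range(n), m):
            best = max(best, sum(M[r, j] for j, r in enumerate(rows)))
    return best


class TestAssignCustom:
    def test_worked_three_cell_example(self):
        # iterative mutual-best commitment: 2-c first, then 3-b, leaving 1-a
        scores = {
            (1, "a"): 0.50, (1, "b"): 0.60, (1, "c"): 0.55,
            (2, "b"): 0.70, (2, "c"): 0.90,
            (3, "a"): 0.40, (3, "b"): 0.80, (3, "c"): 0.85,
        }
        m = TransitionMatrix([1, 2, 3], ["a", "b", "c"], scores,
                             {k: 0.0 for k in scores})
        links, unmatched_r, unmatched_c = lt.assign_custom(m)
        assert links == {(2, "c"), (3, "b"), (1, "a")}
        assert unmatched_r == [] and unmatched_c == []

    def test_diagonal_dominant_matrix_gives_identity(self):
        M = np.full((3, 3), 0.1) + np.eye(3) * 0.8
        links, _, _ = lt.assign_custom(dense_matrix(M))
        assert links == {(0, 100), (1, 101), (2, 102)}

    def test_near_optimal_on_random_dense_matrices(self):
        rng = np.random.default_rng(42)
        total_custom = total_best = 0.0
        for _ in range(100):
            M = rng.uniform(0.01, 1.0, size=(5, 5))
            links, _, _ = lt.assign_custom(dense_matrix(M))
            m = dense_matrix(M)
            total_custom += sum(m.scores[l] for l in links)
            total_best += brute_force_best(M)
        assert total_custom >= 0.95 * total_best

    def test_swap_stage_improves_greedy_conflicts(self):
        # row 0 grabs column 0 greedily; the swap stage must trade targets
        M = np.array([[0.9, 0.8], [0.85, 0.1]])
        links, _, _ = lt.assign_custom(dense_matrix(M))
        assert links == {(0, 101), (1, 100)}


class TestAssignHungarian:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        M = rng.uniform(0.01, 1.0, size=(n, m))
        matrix = dense_matrix(M)
        links, _, _ = lt.assign_hungarian(matrix)
        total = sum(matrix.scores[l] for l in links)
        assert total == pytest.approx(brute_force_best(M))

    def test_square_diagonal_gives_identity(self):
        links, _, _ = lt.assign_hungarian(dense_matrix(np.eye(4) * 0.9 + 0.01))
        assert links == {(i, 100 + i) for i in range(4)}

    def test_rectangular_matrix_leaves_extras_unmatched(self):
        M = np.random.default_rng(0).uniform(0.1, 1.0, size=(3, 5))
        links, unmatched_r, unmatched_c = lt.assign_hungarian(dense_matrix(M))
        assert len(links) == 3
        assert unmatched_r == []
        assert len(unmatched_c) == 2

    def test_gated_out_pairs_never_assigned(self):
        m = TransitionMatrix([0, 1], [100, 101], {(0, 100): 0.9}, {(0, 100): 0.0})
        links, unmatched_r, unmatched_c = lt.assign_hungarian(m)
        assert links == {(0, 100)}
        assert unmatched_r == [1] and unmatched_c == [101]


class TestTrackMovie:
    def test_single_drifting_cell_yields_one_full_track(self):
        frames = [
            frame_df([obs_row(1, 10 + 3 * f, 20, frame=f)]) for f in range(20)
        ]
        tracks = lt.track_movie(frames, lt.TrackingParameters())
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_empty_movie_gives_empty_result(self):
        assert lt.track_movie([], lt.TrackingParameters()) == []

    def test_translation_invariance(self, small_features):
        frames = lt.frames_from_features(small_features)[:5]
        p = lt.TrackingParameters()
        base = links_from_tracks(lt.track_movie(frames, p))
        shifted = []
        for df in frames:
            df2 = df.copy()
            df2["x"] += 37.0
            df2["y"] -= 11.0
            shifted.append(df2)
        assert links_from_tracks(lt.track_movie(shifted, p)) == base

    def test_intensity_disambiguates_crossing_cells(self):
        # two cells approach and swap relative positions; distance alone
        # would link each to the other's position, intensity resolves it
        a0 = obs_row(1, 10, 10, mean_hoechst=60.0, area=120.0)
        b0 = obs_row(2, 22, 10, mean_hoechst=160.0, area=220.0,
                     std_hoechst=12.0, moment2_area_norm=2200.0)
        a1 = obs_row(1, 20, 10, frame=1, mean_hoechst=62.0, area=122.0)
        b1 = obs_row(2, 12, 10, frame=1, mean_hoechst=158.0, area=218.0,
                     std_hoechst=12.0, moment2_area_norm=2180.0)
        tracks = lt.track_movie(
            [frame_df([a0, b0]), frame_df([a1, b1])], lt.TrackingParameters()
        )
        links = links_from_tracks(tracks)
        assert links == {(0, 1, 1), (0, 2, 2)}

    def test_recovers_ground_truth_links(self, small_tracking, true_links):
        frames, params, tracks = small_tracking
        pred = links_from_tracks(tracks)
        non_division = {l for l in true_links}
        recovered = len(pred & non_division) / len(non_division)
        assert recovered >= 0.9


class TestOptimizeParameters:
    def test_zero_iterations_returns_initial(self, small_features):
        frames = lt.frames_from_features(small_features)[:3]
        p0 = lt.TrackingParameters()
        p, trace = lt.optimize_parameters(frames, p0, max_iter=0)
        assert p.weights == p0.weights and p.thresholds == p0.thresholds
        assert len(trace) == 1

    def test_perfect_objective_unchanged(self, small_tracking, true_links):
        frames, params, tracks = small_tracking
        sub = frames[:3]
        gold = {l for l in true_links if l[0] < 2}
        pred = links_from_tracks(lt.track_movie(sub, params))
        if gold <= pred:  # already perfect on this window
            p, trace = lt.optimize_parameters(
                sub, params, objective="gold_accuracy", gold_links=gold, max_iter=2
            )
            assert trace[-1] == 1.0

    def test_corrupted_weight_recovers(self, small_features, true_links):
        frames = lt.frames_from_features(small_features)[:4]
        gold = {l for l in true_links if l[0] < 3}
        thresholds, gate = lt.estimate_thresholds(frames)
        p0 = lt.TrackingParameters(thresholds=thresholds, distance_gate=gate)
        p0.weights["distance"] = 0.01
        p0.thresholds["distance"] *= 0.05  # cripple the distance feature

        def accuracy(p):
            pred = links_from_tracks(lt.track_movie(frames, p))
            return len(pred & gold) / len(gold)

        p, trace = lt.optimize_parameters(
            frames, p0, objective="gold_accuracy", gold_links=gold, max_iter=3
        )
        assert accuracy(p) >= accuracy(p0)
        assert trace[-1] >= trace[0]

    def test_gold_objective_requires_gold(self, small_features):
        frames = lt.frames_from_features(small_features)[:2]
        with pytest.raises(ValueError):
            lt.optimize_parameters(
                frames, lt.TrackingParameters(), objective="gold_accuracy"
            )
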