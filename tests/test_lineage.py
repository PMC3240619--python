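import numpy as np
import pandas as pd
import pytest

import lineagetrack as lt
from lineagetrack.lineage import DivisionParams, _obs_lookup
from lineagetrack.tracking import Track


def obs(frame, cell_id, x, y, intensity, area, gfp=np.nan):
    return {
        "frame": frame, "cell_id": cell_id, "x": float(x), "y": float(y),
        "integrated_hoechst": float(intensity), "area": float(area),
        "mean_hoechst": float(intensity) / float(area),
        "integrated_gfp": gfp,
    }


def features_of(rows):
    return pd.DataFrame(rows)


def single_division_scene():
    """A parent halves into two daughters; one bystander cell nearby."""
    rows = [
        obs(0, 1, 50, 50, 20000, 150, gfp=8000),
        obs(0, 2, 120, 120, 21000, 160, gfp=6000),
        obs(1, 1, 52, 50, 20100, 152, gfp=8100),   # parent pre-division
        obs(1, 2, 122, 120, 21050, 158, gfp=6050),
        obs(2, 11, 48, 44, 10400, 84, gfp=4100),   # daughters
        obs(2, 12, 56, 57, 9700, 82, gfp=4000),
        obs(2, 2, 124, 121, 20980, 161, gfp=6060),
    ]
    tracks = [
        Track(1, [(0, 1), (1, 1), (2, 11)]),  # tracker follows parent onto d1
        Track(2, [(0, 2), (1, 2), (2, 2)]),
        Track(3, [(2, 12)]),
    ]
    return features_of(rows), tracks


class TestCandidates:
    def test_halving_transition_is_flagged(self):
        features, tracks = single_division_scene()
        cands = lt.detect_division_candidates(tracks, features, DivisionParams())
        assert (tracks[0], 1) in cands

    def test_small_fluctuations_not_flagged(self):
        rows = [obs(f, 1, 50 + f, 50, 20000 * (1 + 0.05 * (-1) ** f), 150) for f in range(4)]
        tracks = [Track(1, [(f, 1) for f in range(4)])]
        cands = lt.detect_division_candidates(tracks, features_of(rows), DivisionParams())
        assert cands == []

    def test_intensity_drop_without_area_drop_not_flagged(self):
        rows = [
            obs(0, 1, 50, 50, 20000, 150),
            obs(1, 1, 52, 50, 13000, 170),  # -35% intensity, area grows
        ]
        tracks = [Track(1, [(0, 1), (1, 1)])]
        cands = lt.detect_division_candidates(tracks, features_of(rows), DivisionParams())
        assert cands == []

    def test_termination_with_two_nearby_starts_is_candidate(self):
        rows = [
            obs(0, 1, 50, 50, 20000, 150),
            obs(1, 11, 45, 47, 10000, 82),
            obs(1, 12, 56, 54, 10000, 83),
        ]
        tracks = [
            Track(1, [(0, 1)]),
            Track(2, [(1, 11)]),
            Track(3, [(1, 12)]),
        ]
        cands = lt.detect_division_candidates(tracks, features_of(rows), DivisionParams())
        assert (tracks[0], 0) in cands


class TestScoreDaughterPair:
    def test_perfect_split_scores_one(self):
        p = DivisionParams()
        parent = pd.Series(obs(0, 1, 0, 0, 20000, 150))
        d1 = pd.Series(obs(1, 2, -5, 0, 10000, 75))
        d2 = pd.Series(obs(1, 3, 5, 0, 10000, 75))
        assert lt.score_daughter_pair(parent, d1, d2, p) == pytest.approx(1.0)

    def test_true_pair_beats_daughter_plus_bystander(self):
        p = DivisionParams()
        parent = pd.Series(obs(0, 1, 0, 0, 20000, 150))
        d1 = pd.Series(obs(1, 2, -5, 0, 9000, 82))    # 45% of parent intensity
        d2 = pd.Series(obs(1, 3, 5, 0, 11000, 82))    # 55%
        bystander = pd.Series(obs(1, 4, 8, 0, 20000, 150))
        true_score = lt.score_daughter_pair(parent, d1, d2, p)
        false_score = lt.score_daughter_pair(parent, d1, bystander, p)
        assert true_score > false_score
        assert true_score > 0.8

    def test_identical_daughter_rejected(self):
        p = DivisionParams()
        parent = pd.Series(obs(0, 1, 0, 0, 20000, 150))
        d = pd.Series(obs(1, 2, -5, 0, 10000, 75))
        with pytest.raises(ValueError):
            lt.score_daughter_pair(parent, d, d, p)


class TestDetectDivisions:
    def test_single_clean_division_yields_one_event(self):
        features, tracks = single_division_scene()
        events, tracks = lt.detect_divisions(tracks, features, DivisionParams())
        assert len(events) == 1
        ev = events[0]
        assert ev.frame == 1
        assert ev.division_score >= 0.5
        # the parent track was split at the division frame
        by_id = {t.track_id: t for t in tracks}
        parent = by_id[ev.parent_track_id]
        assert parent.observations[-1] == (1, 1)
        for d in ev.daughter_track_ids:
            assert by_id[d].parent_track_id == ev.parent_track_id
            assert by_id[d].observations[0][0] == 2

    def test_daughters_beyond_radius_not_considered(self):
        features, tracks = single_division_scene()
        p = DivisionParams(daughter_search_radius=2.0)
        events, _ = lt.detect_divisions(tracks, features, p)
        assert events == []

    def test_high_cutoff_suppresses_poor_pairs(self):
        features, tracks = single_division_scene()
        p = DivisionParams(min_division_score=0.999999)
        events, _ = lt.detect_divisions(tracks, features, p)
        assert events == []

    def test_deterministic(self):
        f1, t1 = single_division_scene()
        f2, t2 = single_division_scene()
        e1, _ = lt.detect_divisions(t1, f1, DivisionParams())
        e2, _ = lt.detect_divisions(t2, f2, DivisionParams())
        assert [(e.parent_track_id, e.frame, e.daughter_track_ids) for e in e1] == [
            (e.parent_track_id, e.frame, e.daughter_track_ids) for e in e2
        ]


class TestBuildLineages:
    def test_no_divisions_gives_singleton_forest(self):
        tracks = [Track(1, [(0, 1)]), Track(2, [(0, 2)])]
        forest = lt.build_lineages(tracks, [])
        assert sorted(forest.roots()) == [1, 2]
        assert forest.graph.number_of_edges() == 0

    def test_two_sequential_divisions_give_three_generations(self):
        tracks = [Track(i, [(i, i)]) for i in range(1, 6)]
        events = [
            lt.DivisionEvent(1, 0, (2, 3), 0.9),
            lt.DivisionEvent(2, 1, (4, 5), 0.8),
        ]
        forest = lt.build_lineages(tracks, events)
        assert forest.roots() == [1]
        assert forest.depth(1) == 3

    def test_daughter_claimed_twice_rejected(self):
        tracks = [Track(i, [(0, i)]) for i in range(1, 6)]
        events = [
            lt.DivisionEvent(1, 0, (3, 4), 0.9),
            lt.DivisionEvent(2, 0, (4, 5), 0.8),
        ]
        with pytest.raises(ValueError):
            lt.build_lineages(tracks, events)

    def test_link_count_equals_non_roots(self, small_tracking, small_features):
        _, _, tracks = small_tracking
        events, tracks = lt.detect_divisions(
            [Track(t.track_id, list(t.observations), t.parent_track_id) for t in tracks],
            small_features,
            DivisionParams(),
        )
        forest = lt.build_lineages(tracks, events, small_features)
        non_roots = sum(1 for n in forest.graph.nodes if forest.graph.in_degree(n) == 1)
        assert forest.graph.number_of_edges() == non_roots
        assert len(forest.timecourses) > 0


class TestPartitionStats:
    def test_exact_even_splits(self):
        rng = np.random.default_rng(0)
        parents = rng.uniform(10000, 30000, 50)
        values = pd.DataFrame(
            {"parent": parents, "daughter1": parents / 2, "daughter2": parents / 2}
        )
        stats = lt.division_partition_stats(values)
        assert stats.sum_pct_mean == pytest.approx(100.0)
        assert stats.diff_pct_mean == pytest.approx(0.0)
        assert stats.r_squared == pytest.approx(1.0)

    def test_single_event_r2_undefined(self):
        values = pd.DataFrame({"parent": [100.0], "daughter1": [55.0], "daughter2": [45.0]})
        stats = lt.division_partition_stats(values)
        assert stats.n == 1
        assert np.isnan(stats.r_squared)
        assert stats.sum_pct_mean == pytest.approx(100.0)

    def test_recovers_programmed_asymmetry(self):
        # asymmetry parameter is E|d1-d2|/parent: draw splits the way the
        # simulator does and confirm the statistic matches
        rng = np.random.default_rng(5)
        n = 400
        parents = rng.uniform(15000, 25000, n)
        delta = 0.06 * np.sqrt(np.pi / 2) * rng.standard_normal(n)
        s = np.clip(0.5 + delta / 2, 0.25, 0.75)
        values = pd.DataFrame(
            {"parent": parents, "daughter1": s * parents, "daughter2": (1 - s) * parents}
        )
        stats = lt.division_partition_stats(values)
        assert stats.diff_pct_mean == pytest.approx(6.0, abs=1.0)
        assert stats.sum_pct_mean == pytest.approx(100.0, abs=1e-9)

    def test_collect_values_from_detected_events(self):
        features, tracks = single_division_scene()
        events, tracks = lt.detect_divisions(tracks, features, DivisionParams())
        values = lt.collect_division_values(events, tracks, features, "integrated_hoechst")
        assert len(values) == 1
        assert values["parent"].iloc[0] == pytest.approx(20100)
        assert set(values.iloc[0][["daughter1", "daughter2"]]) == {10400.0, 9700.0}
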