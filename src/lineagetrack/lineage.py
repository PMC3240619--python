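"""Division detection and lineage reconstruction.

A division announces itself in the nuclear channel: the chromatin marker
segregates into the daughters, so the parent's integrated intensity and
nuclear area both drop sharply (by at least ~25%) across the transition.
Candidate parent endpoints found this way are resolved into division
events by scoring daughter pairs: the two daughters should resemble each
other, and a 'composite cell' whose area and intensity are the daughter
sums should resemble the parent. Both similarities use the tracker's
combined score restricted to integrated intensity (weight 1) and area
(weight 0.25); intensity dominates because it is conserved much more
tightly through division than area.

Accepted events link daughter tracks to their parent; tracks plus
divisions assemble into a lineage forest with per-node fluorescence
time courses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tracking import Track, feature_movement_score


@dataclass
class DivisionParams:
    """Tunables for division detection.

    ``drop_fraction`` is the minimum simultaneous fractional drop of
    integrated intensity and area flagging a candidate.
    ``intensity_threshold_frac``/``area_threshold_frac`` set the sigmoid
    thresholds of the daughter-pair and composite-cell scores as fractions
    of the parent's intensity/area.
    """

    drop_fraction: float = 0.25
    daughter_search_radius: float = 30.0  # px
    intensity_weight: float = 1.0
    area_weight: float = 0.25
    min_division_score: float = 0.5
    intensity_threshold_frac: float = 0.25
    area_threshold_frac: float = 0.25

    def validate(self) -> None:
        if not (0.0 < self.drop_fraction < 1.0):
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.intensity_weight <= 0 or self.area_weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class DivisionEvent:
    parent_track_id: int
    frame: int  # last frame of the parent
    daughter_track_ids: tuple[int, int]
    division_score: float


@dataclass
class LineageForest:
    """Trees over tracks via parent links, with per-node time courses.

    ``graph`` is a directed forest with track ids as nodes and
    parent -> daughter edges. ``timecourses`` has one row per track per
    frame: lineage_id (root track of the tree), track_id, frame,
    integrated_gfp, integrated_hoechst.
    """

    graph: nx.DiGraph
    tracks: dict[int, Track]
    timecourses: pd.DataFrame

    def roots(self) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def depth(self, root: int) -> int:
        """Number of generations in the tree rooted at ``root``."""
        depths = nx.single_source_shortest_path_length(self.graph, root)
        return 1 + max(depths.values())


def _obs_lookup(features: pd.DataFrame) -> dict[tuple[int, int], pd.Series]:
    return {
        (int(r.frame), int(r.cell_id)): r
        for r in features.itertuples(index=False)
    }


def detect_division_candidates(
    tracks: list[Track],
    features: pd.DataFrame,
    p: DivisionParams,
    last_frame: int | None = None,
) -> list[tuple[Track, int]]:
    """Find track positions that may be a parent's final observation.

    A position qualifies when integrated nuclear intensity AND area both
    drop by at least ``drop_fraction`` across the transition out of it
    (the tracker may have followed the parent onto one daughter), or when
    the track terminates before the movie ends with at least two new
    tracks starting nearby in the next frame (the parent may vanish
    between frames during M-phase).

    Returns (track, index of the candidate observation within the track).
    """
    p.validate()
    obs = _obs_lookup(features)
    if last_frame is None:
        last_frame = int(features["frame"].max())
    starts_by_frame: dict[int, list[Track]] = {}
    for tr in tracks:
        starts_by_frame.setdefault(tr.start_frame, []).append(tr)

    candidates: list[tuple[Track, int]] = []
    for tr in tracks:
        for k in range(len(tr.observations) - 1):
            a = obs[tr.observations[k]]
            b = obs[tr.observations[k + 1]]
            int_drop = (a.integrated_hoechst - b.integrated_hoechst) / a.integrated_hoechst
            area_drop = (a.area - b.area) / a.area
            if int_drop >= p.drop_fraction and area_drop >= p.drop_fraction:
                candidates.append((tr, k))
        if tr.end_frame < last_frame:
            end = obs[tr.observations[-1]]
            nearby_starts = [
                s for s in starts_by_frame.get(tr.end_frame + 1, [])
                if math.hypot(
                    obs[s.observations[0]].x - end.x,
                    obs[s.observations[0]].y - end.y,
                ) <= p.daughter_search_radius
            ]
            if len(nearby_starts) >= 2:
                candidates.append((tr, len(tr.observations) - 1))
    return candidates


def score_daughter_pair(parent, d1, d2, p: DivisionParams) -> float:
    """Division score for a candidate daughter pair.

    The score is the product of two combined similarities, each over
    integrated intensity (weight 1) and area (weight 0.25):

    * pair similarity — how alike the two daughters are;
    * composite similarity — how closely a virtual cell with the summed
      daughter area and intensity matches the parent.

    A perfect split (equal daughters whose sums reproduce the parent)
    scores exactly 1. Sigmoid thresholds scale with the parent's own
    intensity and area.
    """
    if d1 is d2 or (
        int(_f(d1, "cell_id", -1)) == int(_f(d2, "cell_id", -2))
        and int(_f(d1, "frame", -1)) == int(_f(d2, "frame", -2))
    ):
        raise ValueError("a daughter pair must consist of two distinct cells")
    t_int = p.intensity_threshold_frac * float(parent.integrated_hoechst)
    t_area = p.area_threshold_frac * float(parent.area)

    def sim(d_int: float, d_area: float) -> float:
        s_i = feature_movement_score(d_int, t_int, 5.0 / t_int)
        s_a = feature_movement_score(d_area, t_area, 5.0 / t_area)
        return s_i**p.intensity_weight * s_a**p.area_weight

    pair = sim(
        abs(float(d1.integrated_hoechst) - float(d2.integrated_hoechst)),
        abs(float(d1.area) - float(d2.area)),
    )
    composite = sim(
        abs(float(d1.integrated_hoechst) + float(d2.integrated_hoechst)
            - float(parent.integrated_hoechst)),
        abs(float(d1.area) + float(d2.area) - float(parent.area)),
    )
    return pair * composite


def _f(obj, name, default):
    try:
        return getattr(obj, name)
    except AttributeError:
        return default


def detect_divisions(
    tracks: list[Track],
    features: pd.DataFrame,
    p: DivisionParams,
) -> tuple[list[DivisionEvent], list[Track]]:
    """Resolve division candidates into events and update track parentage.

    For every candidate parent endpoint, daughter pairs are drawn from new
    tracks starting within ``daughter_search_radius`` in the next frame
    plus the parent track's own continuation; the best-scoring pair is
    accepted when its score reaches ``min_division_score``. Each daughter
    joins at most one division (conflicts go to the higher score, then the
    earlier frame). When the accepted pair includes the parent's
    continuation, the parent track is split at the division frame.

    Returns (events, updated track list). Deterministic for fixed inputs.
    """
    p.validate()
    obs = _obs_lookup(features)
    last_frame = int(features["frame"].max())
    candidates = detect_division_candidates(tracks, features, p, last_frame)
    starts_by_frame: dict[int, list[Track]] = {}
    for tr in tracks:
        starts_by_frame.setdefault(tr.start_frame, []).append(tr)

    # proposals: (frame, score, parent track, obs index, daughter descriptors)
    # where a descriptor is (kind, track, first-observation key)
    proposals = []
    for tr, k in candidates:
        parent = obs[tr.observations[k]]
        f = tr.observations[k][0]
        pool: list[tuple[str, Track, tuple[int, int]]] = []
        for s in starts_by_frame.get(f + 1, []):
            if s is tr:
                continue
            key = s.observations[0]
            first = obs[key]
            if math.hypot(first.x - parent.x, first.y - parent.y) <= p.daughter_search_radius:
                pool.append(("start", s, key))
        if k + 1 < len(tr.observations):
            pool.append(("continuation", tr, tr.observations[k + 1]))
        if len(pool) < 2:
            continue
        best = None
        for da, db in itertools.combinations(pool, 2):
            s = score_daughter_pair(parent, obs[da[2]], obs[db[2]], p)
            if best is None or s > best[0]:
                best = (s, da, db)
        if best is not None and best[0] >= p.min_division_score:
            proposals.append((f, best[0], tr, k, best[1], best[2]))

    # earlier frames first so that a track carrying several generations can
    # be split repeatedly; within a frame higher scores win conflicts
    proposals.sort(key=lambda x: (x[0], -x[1], x[2].track_id))
    events: list[DivisionEvent] = []
    used_parent_obs: set[tuple[int, int]] = set()
    used_daughter_obs: set[tuple[int, int]] = set()
    # track id -> (split index, tail) applied so far, for index redirection
    splits: dict[int, tuple[int, Track]] = {}
    next_id = max((t.track_id for t in tracks), default=0) + 1
    new_tracks = list(tracks)
    for f, score, tr, k, da, db in proposals:
        # redirect (tr, k) through any splits applied since the proposal
        cur, kk = tr, k
        while cur.track_id in splits and kk > splits[cur.track_id][0]:
            ks, tail = splits[cur.track_id]
            cur, kk = tail, kk - (ks + 1)
        parent_key = cur.observations[kk]
        if parent_key in used_parent_obs:
            continue
        d_keys = (da[2], db[2])
        if d_keys[0] in used_daughter_obs or d_keys[1] in used_daughter_obs:
            continue
        daughter_tracks: list[Track] = []
        for kind, dtr, dkey in (da, db):
            if kind == "continuation":
                tail = Track(next_id, cur.observations[kk + 1:],
                             parent_track_id=cur.track_id)
                next_id += 1
                cur.observations = cur.observations[: kk + 1]
                splits[cur.track_id] = (kk, tail)
                new_tracks.append(tail)
                daughter_tracks.append(tail)
            else:
                dtr.parent_track_id = cur.track_id
                daughter_tracks.append(dtr)
        d1, d2 = daughter_tracks
        events.append(
            DivisionEvent(cur.track_id, f, (d1.track_id, d2.track_id), score)
        )
        used_parent_obs.add(parent_key)
        used_daughter_obs.update(d_keys)
    return events, new_tracks


def build_lineages(
    tracks: list[Track],
    divisions: list[DivisionEvent],
    features: pd.DataFrame | None = None,
) -> LineageForest:
    """Assemble tracks and divisions into a lineage forest.

    Rejects malformed input: a daughter claimed by two events, more than
    two daughters per parent, or a cyclic parent structure. When a
    feature table is supplied, per-node fluorescence time courses are
    attached.
    """
    g = nx.DiGraph()
    by_id = {t.track_id: t for t in tracks}
    g.add_nodes_from(by_id)
    for ev in divisions:
        if ev.parent_track_id not in by_id:
            raise ValueError(f"unknown parent track {ev.parent_track_id}")
        for d in ev.daughter_track_ids:
            if d not in by_id:
                raise ValueError(f"unknown daughter track {d}")
            if g.in_degree(d) > 0:
                raise ValueError(f"track {d} claimed by two divisions")
            g.add_edge(ev.parent_track_id, d)
    for n in g.nodes:
        if g.out_degree(n) > 2:
            raise ValueError(f"track {n} has more than two daughters")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("parent links form a cycle")

    rows = []
    if features is not None:
        obs = _obs_lookup(features)
        root_of: dict[int, int] = {}
        for n in nx.topological_sort(g):
            preds = list(g.predecessors(n))
            root_of[n] = root_of[preds[0]] if preds else n
        for tr in tracks:
            for frame, cid in tr.observations:
                o = obs[(frame, cid)]
                rows.append(
                    (root_of[tr.track_id], tr.track_id, frame,
                     float(_f(o, "integrated_gfp", np.nan)),
                     float(o.integrated_hoechst))
                )
    timecourses = pd.DataFrame(
        rows,
        columns=["lineage_id", "track_id", "frame",
                 "integrated_gfp", "integrated_hoechst"],
    )
    return LineageForest(g, by_id, timecourses)


@dataclass
class PartitionStats:
    """Daughter-partition statistics for one fluorescence channel.

    Percentages are relative to the parent's value: ``sum_pct`` summarises
    (d1+d2)/parent and ``diff_pct`` |d1-d2|/parent; standard errors are
    sd/sqrt(n). ``r_squared`` is the squared Pearson correlation between
    the two daughters' values (NaN below two events).
    """

    n: int
    r_squared: float
    sum_pct_mean: float
    sum_pct_sem: float
    diff_pct_mean: float
    diff_pct_sem: float


def division_partition_stats(values: pd.DataFrame) -> PartitionStats:
    """Summarise how a channel partitions between daughters.

    ``values`` must carry one row per division with columns ``parent``,
    ``daughter1`` and ``daughter2`` (channel values for the parent at its
    last frame and the daughters at their first).
    """
    needed = {"parent", "daughter1", "daughter2"}
    if not needed.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(needed)}")
    v = values.dropna(subset=sorted(needed))
    v = v[v["parent"] > 0]
    n = len(v)
    if n == 0:
        return PartitionStats(0, np.nan, np.nan, np.nan, np.nan, np.nan)
    d1 = v["daughter1"].to_numpy(dtype=float)
    d2 = v["daughter2"].to_numpy(dtype=float)
    par = v["parent"].to_numpy(dtype=float)
    sum_pct = 100.0 * (d1 + d2) / par
    diff_pct = 100.0 * np.abs(d1 - d2) / par
    if n >= 2 and d1.std() > 0 and d2.std() > 0:
        r2 = float(np.corrcoef(d1, d2)[0, 1] ** 2)
    else:
        r2 = np.nan
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return PartitionStats(
        n, r2,
        float(sum_pct.mean()), sem(sum_pct),
        float(diff_pct.mean()), sem(diff_pct),
    )


def collect_division_values(
    events: list[DivisionEvent],
    tracks: list[Track],
    features: pd.DataFrame,
    channel: str = "integrated_hoechst",
) -> pd.DataFrame:
    """Extract (parent, daughter1, daughter2) channel values per event."""
    obs = _obs_lookup(features)
    by_id = {t.track_id: t for t in tracks}
    rows = []
    for ev in events:
        parent = by_id[ev.parent_track_id]
        pk = next(
            (o for o in parent.observations if o[0] == ev.frame),
            parent.observations[-1],
        )
        pv = float(_f(obs[pk], channel, np.nan))
        ds = []
        for did in ev.daughter_track_ids:
            d = by_id[did]
            ds.append(float(_f(obs[d.observations[0]], channel, np.nan)))
        rows.append((pv, ds[0], ds[1]))
    return pd.DataFrame(rows, columns=["parent", "daughter1", "daughter2"])
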