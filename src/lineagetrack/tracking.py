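"""Multi-feature statistical cell tracking.

Frame-to-frame correspondences are scored with a per-feature sigmoidal
movement score

    s(D) = (1 + exp(-alpha*T)) / (1 + exp(alpha*(D - T)))

a falling logistic normalized so that s(0) = 1: a feature difference D
below the threshold T barely costs anything, differences beyond T are
penalized increasingly steeply (alpha sets the steepness). Per-feature
scores are combined across the selected features into one transition
score in [0, 1]; an unchanged cell scores exactly 1.

Scores for all candidate pairs within a distance gate form a sparse
transition matrix per frame transition. Trajectories are assigned either
by a four-stage procedure (mutual-best commitment, greedy completion,
pairwise swap optimization) or by the Hungarian algorithm on a
zero-padded square matrix.

Feature-difference thresholds are estimated from a high percentile of the
differences observed along bootstrap nearest-neighbour links, and weights
and thresholds can be refined by a coordinate-wise hill climb with
escalating perturbation scale.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Features used for tracking by default: displacement plus the four
#: nuclear features with both high variance contribution and high
#: frame-to-frame correlation.
DEFAULT_FEATURES = ("distance", "area", "mean_hoechst", "std_hoechst",
                    "moment2_area_norm")

#: Initial weights: position and intensity correlate most strongly from
#: frame to frame and get 0.9, the remaining features 0.5.
DEFAULT_WEIGHTS = {
    "distance": 0.9,
    "mean_hoechst": 0.9,
    "area": 0.5,
    "std_hoechst": 0.5,
    "moment2_area_norm": 0.5,
}

#: Fallback thresholds (feature units) used when too few bootstrap links
#: are available to estimate percentiles; sized for the default simulator.
DEFAULT_THRESHOLDS = {
    "distance": 10.0,
    "area": 30.0,
    "mean_hoechst": 15.0,
    "std_hoechst": 10.0,
    "moment2_area_norm": 1500.0,
}


@dataclass
class TrackingParameters:
    """Weights, thresholds and gating for the transition score.

    ``alpha`` defaults to 5/T per feature so the score is ~0.5 at D = T
    and ~1 for D << T, one dimensionless shape across features.
    """

    features: tuple[str, ...] = DEFAULT_FEATURES
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    alphas: dict[str, float] = field(default_factory=dict)  # default 5/T
    distance_gate: float = 30.0  # px
    candidate_list_size: int = 5
    combine_mode: str = "power_weighted"  # or "literal_product"

    def alpha(self, f: str) -> float:
        return self.alphas.get(f, 5.0 / self.thresholds[f])

    def validate(self) -> None:
        for f in self.features:
            w = self.weights.get(f)
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"weight for {f!r} must lie in (0, 1]")
            if self.thresholds.get(f, 0.0) <= 0.0:
                raise ValueError(f"threshold for {f!r} must be positive")
        if self.distance_gate < self.thresholds.get("distance", 0.0):
            raise ValueError("distance_gate must be >= the distance threshold")
        if self.combine_mode not in ("power_weighted", "literal_product"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")

    def copy(self) -> "TrackingParameters":
        return dataclasses.replace(
            self,
            weights=dict(self.weights),
            thresholds=dict(self.thresholds),
            alphas=dict(self.alphas),
        )


@dataclass
class TransitionMatrix:
    """Sparse transition scores for one frame transition.

    Entries exist exactly for the cell pairs whose centroid distance is
    within the gate; ``scores[(i, j)]`` is the combined score for cell i
    (frame t) -> cell j (frame t+1), ``dists`` the centroid distance used
    for deterministic tie-breaking.
    """

    row_ids: list[int]
    col_ids: list[int]
    scores: dict[tuple[int, int], float]
    dists: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class Track:
    """A chain of linked observations over strictly consecutive frames."""

    track_id: int
    observations: list[tuple[int, int]]  # (frame, cell_id)
    parent_track_id: int | None = None

    @property
    def start_frame(self) -> int:
        return self.observations[0][0]

    @property
    def end_frame(self) -> int:
        return self.observations[-1][0]

    def __len__(self) -> int:
        return len(self.observations)


def feature_movement_score(D, T: float, alpha: float):
    """Sigmoidal movement score for one feature difference.

    Accepts scalars or arrays; negative differences are treated by
    absolute value. Returns values in (0, 1], exactly 1 at D = 0.
    """
    if T <= 0 or alpha <= 0:
        raise ValueError("threshold and steepness must be positive")
    D = np.abs(np.asarray(D, dtype=np.float64))
    out = (1.0 + np.exp(-alpha * T)) / (1.0 + np.exp(alpha * (D - T)))
    return float(out) if out.ndim == 0 else out


def _get(obs, name: str) -> float:
    """Fetch a feature from a mapping/Series/dataclass-like observation."""
    try:
        return obs[name]
    except (TypeError, KeyError, IndexError):
        return getattr(obs, name)


def combined_score(a, b, p: TrackingParameters) -> float:
    """Combined transition score between observations in consecutive frames.

    In the default ``power_weighted`` mode the per-feature scores are
    combined as prod_f s_f^w(f), so a pair with all feature differences
    zero scores exactly 1. ``literal_product`` mode multiplies w(f)*s_f
    instead. The ``distance`` pseudo-feature uses the Euclidean centroid
    distance as its difference. Features missing on either observation are
    skipped with a warning.
    """
    total = 1.0
    for f in p.features:
        if f == "distance":
            dx = _get(a, "x") - _get(b, "x")
            dy = _get(a, "y") - _get(b, "y")
            D = float(np.hypot(dx, dy))
        else:
            try:
                va, vb = _get(a, f), _get(b, f)
            except AttributeError:
                va = vb = np.nan
            if va is None or vb is None or np.isnan(va) or np.isnan(vb):
                warnings.warn(f"feature {f!r} missing; skipped", stacklevel=2)
                continue
            D = abs(float(va) - float(vb))
        s = feature_movement_score(D, p.thresholds[f], p.alpha(f))
        if p.combine_mode == "power_weighted":
            total *= s ** p.weights[f]
        else:
            total *= p.weights[f] * s
    return total


def build_transition_matrix(
    frame_t: pd.DataFrame, frame_t1: pd.DataFrame, p: TrackingParameters
) -> TransitionMatrix:
    """Score all cell pairs within the distance gate for one transition.

    ``frame_t`` / ``frame_t1`` are feature tables (one row per cell) of
    two consecutive frames. Complexity is linear in cell count times mean
    neighbourhood size thanks to a KD-tree range query.
    """
    p.validate()
    row_ids = [int(i) for i in frame_t["cell_id"]] if len(frame_t) else []
    col_ids = [int(i) for i in frame_t1["cell_id"]] if len(frame_t1) else []
    m = TransitionMatrix(row_ids, col_ids, {}, {})
    if not row_ids or not col_ids:
        return m
    xy_t = frame_t[["x", "y"]].to_numpy(dtype=np.float64)
    xy_t1 = frame_t1[["x", "y"]].to_numpy(dtype=np.float64)
    tree = cKDTree(xy_t1)
    neighbours = tree.query_ball_point(xy_t, r=p.distance_gate)
    # gather pair indices and vectorize the scoring per feature
    ri, ci = [], []
    for i, nbrs in enumerate(neighbours):
        ri.extend([i] * len(nbrs))
        ci.extend(nbrs)
    if not ri:
        return m
    ri = np.asarray(ri)
    ci = np.asarray(ci)
    dists = np.hypot(*(xy_t[ri] - xy_t1[ci]).T)
    total = np.ones(len(ri))
    for f in p.features:
        if f == "distance":
            D = dists
        else:
            if f not in frame_t.columns or f not in frame_t1.columns:
                warnings.warn(f"feature {f!r} missing; skipped", stacklevel=2)
                continue
            va = frame_t[f].to_numpy(dtype=np.float64)[ri]
            vb = frame_t1[f].to_numpy(dtype=np.float64)[ci]
            D = np.abs(va - vb)
        s = feature_movement_score(D, p.thresholds[f], p.alpha(f))
        if p.combine_mode == "power_weighted":
            total *= s ** p.weights[f]
        else:
            total *= p.weights[f] * s
    for i, j, sc, d in zip(ri, ci, total, dists):
        key = (row_ids[i], col_ids[j])
        m.scores[key] = float(sc)
        m.dists[key] = float(d)
    return m


# ---------------------------------------------------------------------------
# threshold estimation

def bootstrap_links(
    frames: list[pd.DataFrame], gate: float = 40.0
) -> list[tuple[int, pd.Series, pd.Series]]:
    """Preliminary greedy nearest-neighbour links for threshold estimation.

    Pairs within ``gate`` pixels are committed one-to-one in order of
    increasing distance. Returns (frame index, obs at t, obs at t+1).
    """
    links = []
    for t in range(len(frames) - 1):
        a, b = frames[t], frames[t + 1]
        if len(a) == 0 or len(b) == 0:
            continue
        xy_a = a[["x", "y"]].to_numpy(dtype=np.float64)
        xy_b = b[["x", "y"]].to_numpy(dtype=np.float64)
        tree = cKDTree(xy_b)
        pairs = []
        for i, nbrs in enumerate(tree.query_ball_point(xy_a, r=gate)):
            for j in nbrs:
                d = float(np.hypot(*(xy_a[i] - xy_b[j])))
                pairs.append((d, i, j))
        pairs.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            links.append((t, a.iloc[i], b.iloc[j]))
    return links


def estimate_thresholds(
    frames: list[pd.DataFrame],
    percentile: float = 95.0,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    bootstrap_gate: float = 40.0,
) -> tuple[dict[str, float], float]:
    """Estimate per-feature thresholds from bootstrap links.

    T(f) is the chosen percentile (valid range 90-99) of the absolute
    feature differences along greedy nearest-neighbour links; the distance
    gate is set to 1.2x the 99th displacement percentile. With fewer than
    50 links the documented defaults are returned with a warning.

    Returns (thresholds, distance_gate).
    """
    if not (90.0 <= percentile <= 99.0):
        raise ValueError("percentile must lie in [90, 99]")
    links = bootstrap_links(frames, gate=bootstrap_gate)
    if len(links) < 50:
        warnings.warn(
            f"only {len(links)} bootstrap links; falling back to default thresholds",
            stacklevel=2,
        )
        return dict(DEFAULT_THRESHOLDS), 3.0 * DEFAULT_THRESHOLDS["distance"]
    diffs: dict[str, list[float]] = {f: [] for f in features}
    for _, a, b in links:
        for f in features:
            if f == "distance":
                diffs[f].append(float(np.hypot(a["x"] - b["x"], a["y"] - b["y"])))
            elif f in a.index and f in b.index:
                diffs[f].append(abs(float(a[f]) - float(b[f])))
    thresholds = {}
    for f in features:
        if diffs[f]:
            t = float(np.percentile(diffs[f], percentile))
            thresholds[f] = t if t > 0 else DEFAULT_THRESHOLDS.get(f, 1.0)
        else:
            thresholds[f] = DEFAULT_THRESHOLDS.get(f, 1.0)
    gate = 1.2 * float(np.percentile(diffs["distance"], 99))
    return thresholds, max(gate, thresholds["distance"])


# ---------------------------------------------------------------------------
# assignment

def _candidates(m: TransitionMatrix, k: int):
    """Top-k forward and backward candidate lists, score-ordered.

    Ties are broken by smaller centroid distance, then smaller cell id.
    """
    fwd: dict[int, list[int]] = {r: [] for r in m.row_ids}
    bwd: dict[int, list[int]] = {c: [] for c in m.col_ids}
    by_row: dict[int, list[tuple]] = {r: [] for r in m.row_ids}
    by_col: dict[int, list[tuple]] = {c: [] for c in m.col_ids}
    for (i, j), s in m.scores.items():
        d = m.dists.get((i, j), 0.0)
        by_row[i].append((-s, d, j))
        by_col[j].append((-s, d, i))
    for i, lst in by_row.items():
        lst.sort()
        fwd[i] = [j for _, _, j in lst[:k]]
    for j, lst in by_col.items():
        lst.sort()
        bwd[j] = [i for _, _, i in lst[:k]]
    return fwd, bwd


def assign_custom(
    m: TransitionMatrix, candidate_list_size: int = 5
) -> tuple[set[tuple[int, int]], list[int], list[int]]:
    """Four-stage trajectory assignment.

    1. Build per-cell candidate lists (top scores, both directions).
    2. Repeatedly commit links where a cell's best available forward
       choice is also its target's best available inbound choice.
    3. Remaining cells take their best still-available forward target.
    4. For pairs of committed links sharing candidate targets, exchange
       targets whenever the summed score improves; iterate to a fixed
       point. Each target is used at most once.

    Returns (links, unmatched row ids, unmatched col ids).
    """
    fwd, bwd = _candidates(m, candidate_list_size)
    links: dict[int, int] = {}
    used_cols: set[int] = set()

    def best_fwd(i):
        for j in fwd[i]:
            if j not in used_cols:
                return j
        return None

    def best_bwd(j):
        for i in bwd[j]:
            if i not in links:
                return i
        return None

    # stage 2: mutual-best commitment to fixed point
    changed = True
    while changed:
        changed = False
        for i in m.row_ids:
            if i in links:
                continue
            j = best_fwd(i)
            if j is not None and best_bwd(j) == i:
                links[i] = j
                used_cols.add(j)
                changed = True

    # stage 3: greedy completion, strongest rows first
    remaining = [i for i in m.row_ids if i not in links and fwd[i]]
    remaining.sort(key=lambda i: -max(m.scores[(i, j)] for j in fwd[i]))
    for i in remaining:
        j = best_fwd(i)
        if j is not None:
            links[i] = j
            used_cols.add(j)

    # stage 4: pairwise swap optimization
    improved = True
    while improved:
        improved = False
        items = sorted(links.items())
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                i1, j1 = items[a]
                i2, j2 = items[b]
                if links.get(i1) != j1 or links.get(i2) != j2:
                    continue
                s12 = m.scores.get((i1, j2))
                s21 = m.scores.get((i2, j1))
                if s12 is None or s21 is None:
                    continue
                if s12 + s21 > m.scores[(i1, j1)] + m.scores[(i2, j2)] + 1e-12:
                    links[i1], links[i2] = j2, j1
                    improved = True

    link_set = {(i, j) for i, j in links.items()}
    unmatched_rows = [i for i in m.row_ids if i not in links]
    unmatched_cols = [j for j in m.col_ids if j not in used_cols]
    return link_set, unmatched_rows, unmatched_cols


def assign_hungarian(
    m: TransitionMatrix,
) -> tuple[set[tuple[int, int]], list[int], list[int]]:
    """Optimal linear assignment on the zero-padded square score matrix.

    Padding entries (and gated-out pairs) carry score 0 and are stripped
    from the result, producing unmatched cells instead of forced links.
    """
    nr, nc = len(m.row_ids), len(m.col_ids)
    if nr == 0 or nc == 0 or not m.scores:
        return set(), list(m.row_ids), list(m.col_ids)
    n = max(nr, nc)
    cost = np.zeros((n, n))
    ridx = {r: i for i, r in enumerate(m.row_ids)}
    cidx = {c: j for j, c in enumerate(m.col_ids)}
    for (r, c), s in m.scores.items():
        cost[ridx[r], cidx[c]] = s
    rows, cols = linear_sum_assignment(cost, maximize=True)
    links = set()
    for i, j in zip(rows, cols):
        if i < nr and j < nc:
            pair = (m.row_ids[i], m.col_ids[j])
            if pair in m.scores and m.scores[pair] > 0:
                links.add(pair)
    matched_r = {i for i, _ in links}
    matched_c = {j for _, j in links}
    return (
        links,
        [r for r in m.row_ids if r not in matched_r],
        [c for c in m.col_ids if c not in matched_c],
    )


# ---------------------------------------------------------------------------
# whole-movie tracking

def track_movie(
    frames: list[pd.DataFrame],
    p: TrackingParameters,
    assigner: str = "custom",
) -> list[Track]:
    """Track a segmented movie frame by frame.

    ``frames`` is a list of per-frame feature tables. Cells unmatched at
    t+1 start new tracks; a track ends when its cell finds no match.
    Frame indices in the returned tracks are positions in ``frames``.
    """
    p.validate()
    if assigner not in ("custom", "hungarian"):
        raise ValueError(f"unknown assigner {assigner!r}")
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # cell_id at current frame -> track
    if not frames:
        return tracks
    for cid in ([] if len(frames[0]) == 0 else frames[0]["cell_id"]):
        tr = Track(len(tracks) + 1, [(0, int(cid))])
        tracks.append(tr)
        active[int(cid)] = tr
    for t in range(len(frames) - 1):
        m = build_transition_matrix(frames[t], frames[t + 1], p)
        if assigner == "custom":
            links, _, unmatched_cols = assign_custom(m, p.candidate_list_size)
        else:
            links, _, unmatched_cols = assign_hungarian(m)
        logger.debug(
            "transition %d->%d: %d pairs scored, %d links, total score %.2f",
            t, t + 1, len(m.scores), len(links),
            sum(m.scores[l] for l in links),
        )
        new_active: dict[int, Track] = {}
        for i, j in links:
            tr = active.get(i)
            if tr is None:  # cell appeared without a track (shouldn't happen)
                tr = Track(len(tracks) + 1, [(t, i)])
                tracks.append(tr)
            tr.observations.append((t + 1, int(j)))
            new_active[int(j)] = tr
        for j in unmatched_cols:
            tr = Track(len(tracks) + 1, [(t + 1, int(j))])
            tracks.append(tr)
            new_active[int(j)] = tr
        active = new_active
    return tracks


def frames_from_features(features: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a multi-frame feature table into per-frame tables."""
    if len(features) == 0:
        return []
    n = int(features["frame"].max()) + 1
    return [
        features[features["frame"] == f].reset_index(drop=True) for f in range(n)
    ]


def total_assigned_score(
    frames: list[pd.DataFrame], p: TrackingParameters, assigner: str = "custom"
) -> float:
    """Sum of assigned transition scores over the movie (internal objective)."""
    total = 0.0
    for t in range(len(frames) - 1):
        m = build_transition_matrix(frames[t], frames[t + 1], p)
        if assigner == "custom":
            links, _, _ = assign_custom(m, p.candidate_list_size)
        else:
            links, _, _ = assign_hungarian(m)
        total += sum(m.scores[l] for l in links)
    return total


def links_from_tracks(tracks: list[Track]) -> set[tuple[int, int, int]]:
    """Flatten tracks to a set of (frame_t, cell_id_t, cell_id_t1) links."""
    out = set()
    for tr in tracks:
        obs = tr.observations
        for k in range(len(obs) - 1):
            out.add((obs[k][0], obs[k][1], obs[k + 1][1]))
    return out


def optimize_parameters(
    frames: list[pd.DataFrame],
    p0: TrackingParameters,
    objective: str = "total_score",
    gold_links: set[tuple[int, int, int]] | None = None,
    max_iter: int = 10,
    assigner: str = "custom",
) -> tuple[TrackingParameters, list[float]]:
    """Coordinate-wise hill climb over weights and thresholds.

    Each parameter is perturbed in turn by +/- 1% of its range (weights:
    range 1; thresholds: range 2x the initial value), keeping changes that
    improve the objective. After a full sweep without improvement the
    perturbation scale doubles, capped at 16%. ``objective`` is either the
    internal ``total_score`` or ``gold_accuracy`` (fraction of gold links
    reproduced; requires ``gold_links``). Deterministic.

    Returns (best parameters, objective trace).
    """
    if objective not in ("total_score", "gold_accuracy"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "gold_accuracy" and not gold_links:
        raise ValueError("gold_accuracy objective requires gold_links")

    def evaluate(p: TrackingParameters) -> float:
        if objective == "total_score":
            return total_assigned_score(frames, p, assigner)
        tracks = track_movie(frames, p, assigner)
        pred = links_from_tracks(tracks)
        return len(pred & gold_links) / max(len(gold_links), 1)

    best = p0.copy()
    best_val = evaluate(best)
    trace = [best_val]
    if max_iter <= 0:
        return best, trace
    names = [("w", f) for f in best.features] + [("t", f) for f in best.features]
    ranges = {("w", f): 1.0 for f in best.features}
    ranges.update({("t", f): 2.0 * best.thresholds[f] for f in best.features})
    scale = 0.01
    for _ in range(max_iter):
        improved = False
        for kind, f in names:
            for sign in (+1.0, -1.0):
                cand = best.copy()
                step = sign * scale * ranges[(kind, f)]
                if kind == "w":
                    cand.weights[f] = float(np.clip(best.weights[f] + step, 0.01, 1.0))
                else:
                    cand.thresholds[f] = max(best.thresholds[f] + step, 1e-6)
                    cand.distance_gate = max(cand.distance_gate,
                                             cand.thresholds.get("distance", 0.0))
                val = evaluate(cand)
                if val > best_val + 1e-12:
                    best, best_val = cand, val
                    trace.append(best_val)
                    improved = True
                    break
        if improved:
            scale = 0.01
        else:
            if scale >= 0.16:
                break
            scale = min(scale * 2.0, 0.16)
    trace.append(best_val)
    return best, trace
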