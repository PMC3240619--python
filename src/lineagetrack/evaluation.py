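"""Benchmark metrics for segmentation, tracking and division detection.

Segmentation is scored both at pixel level (precision, recall, F-score
with a beta weighting, and the kappa overlap index 2|A∩B|/(|A|+|B|)) and
positionally (a detected cell is a true positive when it lies within one
equivalent radius of an unclaimed ground-truth cell). Tracking is scored
by the fraction of gold-standard frame-to-frame links reproduced and by
the longest continuously tracked section per gold track, aggregated as a
percentage of all steps. Divisions are matched by parent position and
frame, with a separate category for divisions detected at the right place
but with wrong daughters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .tracking import Track

logger = logging.getLogger(__name__)


@dataclass
class PixelScore:
    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    F_beta: float
    kappa: float


@dataclass
class TrackScore:
    total_links: int
    correct_links: int
    longest_correct_chain: int
    accuracy_pct: float
    longest_chain_pct: float


@dataclass
class DivisionScore:
    correct: int
    wrong_daughters: int  # division matched, daughters misassigned
    spurious: int  # detected where none occurred
    missed: int


def pixel_scores(pred: np.ndarray, truth: np.ndarray, beta: float = 1.0) -> PixelScore:
    """Pixel-level foreground agreement between two label masks.

    beta weights recall against precision in the F-score; beta = 1 weighs
    them equally. Two empty masks agree vacuously and score 1 throughout.
    """
    if pred.shape != truth.shape:
        raise ValueError("masks differ in shape")
    p = np.asarray(pred) > 0
    t = np.asarray(truth) > 0
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    if tp + fp + fn == 0:
        return PixelScore(tp, fp, tn, fn, 1.0, 1.0, 1.0, 1.0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    b2 = beta * beta
    denom = b2 * precision + recall
    f = (1 + b2) * precision * recall / denom if denom else 0.0
    kappa = 2 * tp / (p.sum() + t.sum()) if (p.sum() + t.sum()) else 1.0
    return PixelScore(tp, fp, tn, fn, precision, recall, f, float(kappa))


@dataclass
class PositionalScore:
    TP: int
    FP: int
    FN: int
    fn_rate: float  # of truth count
    fp_rate: float  # of predicted count


def positional_accuracy(
    pred_xy: np.ndarray,
    pred_radii: np.ndarray,
    truth_xy: np.ndarray,
) -> PositionalScore:
    """Detection accuracy by one-to-one centre matching.

    A predicted cell is a true positive when it can be matched (greedily,
    by increasing distance) to a ground-truth cell within one predicted
    equivalent radius; unmatched predictions are false positives and
    unmatched truth cells false negatives.
    """
    pred_xy = np.atleast_2d(np.asarray(pred_xy, dtype=float))
    truth_xy = np.atleast_2d(np.asarray(truth_xy, dtype=float))
    radii = np.asarray(pred_radii, dtype=float).ravel()
    npred = 0 if pred_xy.size == 0 else len(pred_xy)
    ntruth = 0 if truth_xy.size == 0 else len(truth_xy)
    if npred == 0 or ntruth == 0:
        return PositionalScore(
            0, npred, ntruth,
            1.0 if ntruth else 0.0,
            1.0 if npred else 0.0,
        )
    tree = cKDTree(truth_xy)
    pairs = []
    for i in range(npred):
        for j in tree.query_ball_point(pred_xy[i], r=radii[i]):
            d = float(np.hypot(*(pred_xy[i] - truth_xy[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    for d, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
    tp = len(used_p)
    fp = npred - tp
    fn = ntruth - tp
    return PositionalScore(tp, fp, fn, fn / ntruth, fp / npred)


def _track_positions(tracks: list[Track], features: pd.DataFrame) -> pd.DataFrame:
    """(track_id, frame, cell_id, x, y) rows for predicted tracks."""
    lookup = {
        (int(r.frame), int(r.cell_id)): (float(r.x), float(r.y))
        for r in features.itertuples(index=False)
    }
    rows = []
    for tr in tracks:
        for frame, cid in tr.observations:
            x, y = lookup[(frame, cid)]
            rows.append((tr.track_id, frame, cid, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "cell_id", "x", "y"])


def tracking_accuracy(
    pred: pd.DataFrame | list[Track],
    gold: pd.DataFrame,
    match_radius: float = 7.0,
    features: pd.DataFrame | None = None,
) -> TrackScore:
    """Fraction of gold links reproduced, and longest correct sections.

    ``gold`` (and ``pred`` when given as a table) carry one row per cell
    per frame with columns track_id, frame, x, y. Each gold position is
    mapped to the nearest predicted cell in its frame within
    ``match_radius``; a gold link is correct iff both endpoints map to
    consecutive members of the same predicted track. When two gold cells
    in a frame map to the same predicted cell, their links are scored
    incorrect. The longest run of consecutive correct links per gold track
    is summed and reported as a percentage of all gold links. Invariant
    under relabelling of track ids in either input.
    """
    if isinstance(pred, list):
        if features is None:
            raise ValueError("features table required when pred is a track list")
        pred = _track_positions(pred, features)
    frames = sorted(set(gold["frame"].astype(int)))
    pred_by_frame = {f: df.reset_index(drop=True) for f, df in pred.groupby("frame")}

    # map gold (track, frame) -> predicted (track_id, position-in-track)
    order_in_track: dict[tuple[int, int], int] = {}
    for tid, df in pred.groupby("track_id"):
        for pos, (_, row) in enumerate(df.sort_values("frame").iterrows()):
            order_in_track[(int(tid), int(row["frame"]))] = pos

    mapping: dict[tuple[int, int], int | None] = {}
    pred_track_of: dict[tuple[int, int], int] = {}
    for f in frames:
        gf = gold[gold["frame"] == f]
        pf = pred_by_frame.get(f)
        if pf is None or len(pf) == 0:
            for gt in gf["track_id"]:
                mapping[(int(gt), f)] = None
            continue
        tree = cKDTree(pf[["x", "y"]].to_numpy(dtype=float))
        claims: dict[int, list[int]] = {}
        for _, row in gf.iterrows():
            d, j = tree.query([row["x"], row["y"]], k=1)
            key = (int(row["track_id"]), f)
            if d <= match_radius:
                mapping[key] = int(j)
                claims.setdefault(int(j), []).append(int(row["track_id"]))
            else:
                mapping[key] = None
        for j, claimants in claims.items():
            if len(claimants) > 1:  # ambiguous: score all involved incorrect
                logger.debug("frame %d: %d gold cells map to one prediction", f, len(claimants))
                for gt in claimants:
                    mapping[(gt, f)] = None
        for key, j in mapping.items():
            if key[1] == f and j is not None:
                row = pf.iloc[j]
                pred_track_of[key] = int(row["track_id"])
                mapping[key] = (int(row["track_id"]), int(row["frame"]))

    total = 0
    correct = 0
    longest_sum = 0
    for gt, df in gold.groupby("track_id"):
        df = df.sort_values("frame")
        fs = df["frame"].astype(int).tolist()
        run = best_run = 0
        for a, b in zip(fs[:-1], fs[1:]):
            if b != a + 1:
                run = 0
                continue
            total += 1
            ma = mapping.get((int(gt), a))
            mb = mapping.get((int(gt), b))
            ok = (
                ma is not None and mb is not None
                and ma[0] == mb[0]
                and order_in_track.get((ma[0], b), -99)
                == order_in_track.get((ma[0], a), 99) + 1
            )
            if ok:
                correct += 1
                run += 1
                best_run = max(best_run, run)
            else:
                run = 0
        longest_sum += best_run
    if total == 0:
        return TrackScore(0, 0, 0, 0.0, 0.0)
    return TrackScore(
        total, correct, longest_sum,
        100.0 * correct / total, 100.0 * longest_sum / total,
    )


DIVISION_TABLE_COLUMNS = ["frame", "parent_x", "parent_y",
                          "d1_x", "d1_y", "d2_x", "d2_y"]


def division_events_table(events, tracks: list[Track], features: pd.DataFrame) -> pd.DataFrame:
    """Positions table for detected division events (see division_accuracy)."""
    lookup = {
        (int(r.frame), int(r.cell_id)): (float(r.x), float(r.y))
        for r in features.itertuples(index=False)
    }
    by_id = {t.track_id: t for t in tracks}
    rows = []
    for ev in events:
        parent = by_id[ev.parent_track_id]
        pk = next(o for o in parent.observations if o[0] == ev.frame)
        px, py = lookup[pk]
        dpos = [lookup[by_id[d].observations[0]] for d in ev.daughter_track_ids]
        rows.append((ev.frame, px, py, *dpos[0], *dpos[1]))
    return pd.DataFrame(rows, columns=DIVISION_TABLE_COLUMNS)


def true_division_table(divisions: pd.DataFrame, positions: pd.DataFrame) -> pd.DataFrame:
    """Positions table for a simulator's ground-truth division set."""
    lookup = {
        (int(r.frame), int(r.cell_id)): (float(r.x), float(r.y))
        for r in positions.itertuples(index=False)
    }
    rows = []
    for r in divisions.itertuples(index=False):
        f = int(r.frame)
        px, py = lookup[(f, int(r.parent_id))]
        d1 = lookup[(f + 1, int(r.daughter1_id))]
        d2 = lookup[(f + 1, int(r.daughter2_id))]
        rows.append((f, px, py, *d1, *d2))
    return pd.DataFrame(rows, columns=DIVISION_TABLE_COLUMNS)


def division_accuracy(
    pred_events: pd.DataFrame,
    true_events: pd.DataFrame,
    radius: float = 15.0,
    frame_tolerance: int = 1,
) -> DivisionScore:
    """Match detected divisions against the truth.

    Event tables carry one row per division: frame, parent_x, parent_y,
    d1_x, d1_y, d2_x, d2_y. A predicted event matches a true one when the
    parents coincide within ``radius`` and the frames within
    ``frame_tolerance``; among matched events, the daughters count as
    correct when they pair off with the true daughters within ``radius``.
    """
    used_true: set[int] = set()
    correct = wrong = 0
    for _, pe in pred_events.iterrows():
        best = None
        for ti, te in true_events.iterrows():
            if ti in used_true:
                continue
            if abs(int(pe["frame"]) - int(te["frame"])) > frame_tolerance:
                continue
            d = math.hypot(pe["parent_x"] - te["parent_x"], pe["parent_y"] - te["parent_y"])
            if d <= radius and (best is None or d < best[0]):
                best = (d, ti, te)
        if best is None:
            continue
        _, ti, te = best
        used_true.add(ti)
        # daughters correct if they pair off one-to-one within radius
        d_pred = [(pe["d1_x"], pe["d1_y"]), (pe["d2_x"], pe["d2_y"])]
        d_true = [(te["d1_x"], te["d1_y"]), (te["d2_x"], te["d2_y"])]

        def _d(a, b):
            return math.hypot(a[0] - b[0], a[1] - b[1])

        ok = (
            max(_d(d_pred[0], d_true[0]), _d(d_pred[1], d_true[1])) <= radius
            or max(_d(d_pred[0], d_true[1]), _d(d_pred[1], d_true[0])) <= radius
        )
        if ok:
            correct += 1
        else:
            wrong += 1
    spurious = len(pred_events) - correct - wrong
    missed = len(true_events) - len(used_true)
    return DivisionScore(correct, wrong, spurious, missed)
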