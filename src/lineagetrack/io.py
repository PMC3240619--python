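"""Movie, mask and table input/output plus the end-to-end pipeline.

All tables are plain CSV with a one-line header; coordinates are 0-based
pixel indices with origin at the top-left, x = column and y = row.
Configuration files are flat ``key=value`` text.
"""

from __future__ import annotations

import glob as globmod
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import lineage as lin
from . import segmentation as seg
from . import tracking as trk

logger = logging.getLogger(__name__)


@dataclass
class MovieHandle:
    """Lazy accessor for a multi-channel movie.

    Frames are loaded per channel on first access; all channels must have
    equal frame counts and dimensions.
    """

    channel_paths: dict[str, list[Path]]  # per-channel page sources
    n_frames: int
    shape: tuple[int, int]  # (H, W)
    pixel_size_um: float | None = None
    frame_interval_min: float | None = None
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def channels(self) -> list[str]:
        return list(self.channel_paths)

    def stack(self, channel: str) -> np.ndarray:
        if channel not in self._cache:
            paths = self.channel_paths[channel]
            if len(paths) == 1:
                arr = tifffile.imread(paths[0])
                if arr.ndim == 2:
                    arr = arr[None]
            else:
                arr = np.stack([tifffile.imread(p) for p in paths])
            self._cache[channel] = arr
        return self._cache[channel]

    def frame(self, channel: str, index: int) -> np.ndarray:
        return self.stack(channel)[index]


def _expand(path_or_glob: str | Path | list) -> list[Path]:
    if isinstance(path_or_glob, (list, tuple)):
        return [Path(p) for p in path_or_glob]
    s = str(path_or_glob)
    if any(ch in s for ch in "*?["):
        return [Path(p) for p in sorted(globmod.glob(s))]
    return [Path(s)]


def read_movie(channel_paths: dict[str, str | Path | list]) -> MovieHandle:
    """Open a movie from per-channel TIFF stacks or per-frame file globs.

    Channels with mismatched frame counts or dimensions raise a ValueError
    naming every channel's count.
    """
    counts: dict[str, int] = {}
    shapes: dict[str, tuple[int, int]] = {}
    sources: dict[str, list[Path]] = {}
    for name, spec in channel_paths.items():
        paths = _expand(spec)
        if not paths:
            raise ValueError(f"channel {name!r}: no files match {spec!r}")
        sources[name] = paths
        if len(paths) == 1:
            with tifffile.TiffFile(paths[0]) as tf:
                counts[name] = len(tf.pages)
                shapes[name] = tf.pages[0].shape[-2:]
        else:
            counts[name] = len(paths)
            with tifffile.TiffFile(paths[0]) as tf:
                shapes[name] = tf.pages[0].shape[-2:]
    if len(set(counts.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in counts.items())
        raise ValueError(f"channels have mismatched frame counts: {detail}")
    if len(set(shapes.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in shapes.items())
        raise ValueError(f"channels have mismatched dimensions: {detail}")
    n = next(iter(counts.values()))
    shape = next(iter(shapes.values()))
    return MovieHandle(sources, n, shape)


# ---------------------------------------------------------------------------
# configuration

def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value configuration file ('#' starts a comment)."""
    cfg: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def write_config(path: str | Path, cfg: dict) -> None:
    lines = [f"{k}={v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def tracking_params_from_config(cfg: dict[str, str]) -> trk.TrackingParameters:
    """Build TrackingParameters from flat config keys.

    Recognised keys: ``features`` (comma list), ``weight.<f>``,
    ``threshold.<f>``, ``alpha.<f>``, ``distance_gate``,
    ``candidate_list_size``, ``combine_mode``.
    """
    p = trk.TrackingParameters()
    if "features" in cfg:
        p.features = tuple(f.strip() for f in cfg["features"].split(",") if f.strip())
    for key, value in cfg.items():
        if key.startswith("weight."):
            p.weights[key[len("weight."):]] = float(value)
        elif key.startswith("threshold."):
            p.thresholds[key[len("threshold."):]] = float(value)
        elif key.startswith("alpha."):
            p.alphas[key[len("alpha."):]] = float(value)
    if "distance_gate" in cfg:
        p.distance_gate = float(cfg["distance_gate"])
    if "candidate_list_size" in cfg:
        p.candidate_list_size = int(cfg["candidate_list_size"])
    if "combine_mode" in cfg:
        p.combine_mode = cfg["combine_mode"]
    return p


def tracking_params_to_config(p: trk.TrackingParameters) -> dict[str, str]:
    cfg: dict[str, str] = {"features": ",".join(p.features)}
    for f in p.features:
        cfg[f"weight.{f}"] = repr(p.weights[f])
        cfg[f"threshold.{f}"] = repr(p.thresholds[f])
        if f in p.alphas:
            cfg[f"alpha.{f}"] = repr(p.alphas[f])
    cfg["distance_gate"] = repr(p.distance_gate)
    cfg["candidate_list_size"] = str(p.candidate_list_size)
    cfg["combine_mode"] = p.combine_mode
    return cfg


# ---------------------------------------------------------------------------
# track tables

def tracks_to_dataframe(
    tracks: list[trk.Track], features: pd.DataFrame
) -> pd.DataFrame:
    """Flatten tracks to (track_id, frame, cell_id, x, y, parent_track_id)."""
    lookup = {
        (int(r.frame), int(r.cell_id)): (float(r.x), float(r.y))
        for r in features.itertuples(index=False)
    }
    rows = []
    for tr in tracks:
        for frame, cid in tr.observations:
            x, y = lookup[(frame, cid)]
            rows.append(
                (tr.track_id, frame, cid, x, y,
                 -1 if tr.parent_track_id is None else tr.parent_track_id)
            )
    df = pd.DataFrame(
        rows, columns=["track_id", "frame", "cell_id", "x", "y", "parent_track_id"]
    )
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def tracks_from_dataframe(df: pd.DataFrame) -> list[trk.Track]:
    """Inverse of :func:`tracks_to_dataframe`."""
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        parent = int(sub["parent_track_id"].iloc[0])
        tracks.append(
            trk.Track(
                int(tid),
                [(int(f), int(c)) for f, c in zip(sub["frame"], sub["cell_id"])],
                None if parent < 0 else parent,
            )
        )
    return tracks


def divisions_to_dataframe(
    events: list[lin.DivisionEvent],
) -> pd.DataFrame:
    rows = [
        (e.parent_track_id, e.frame, e.daughter_track_ids[0],
         e.daughter_track_ids[1], e.division_score)
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["parent_track_id", "frame", "daughter1_track_id",
                 "daughter2_track_id", "score"],
    )


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(
    cfg: dict[str, str],
    out_dir: str | Path,
    resume: bool = True,
) -> dict[str, Path]:
    """Segment, track and reconstruct lineages for a configured movie.

    ``cfg`` must name the movie inputs (``hoechst``, optionally ``gfp``,
    as TIFF stacks or globs) and may override segmentation and tracking
    parameters. Stages are resumable: existing intermediate CSVs in
    ``out_dir`` are reused unless ``resume`` is false. Every parameter
    value used is written to ``run_log.cfg``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "masks": out / "masks.tif",
        "features": out / "features.csv",
        "tracks": out / "tracks.csv",
        "divisions": out / "divisions.csv",
        "lineages": out / "lineages.csv",
        "run_log": out / "run_log.cfg",
    }
    if "hoechst" not in cfg:
        raise ValueError("pipeline config must name the 'hoechst' channel input")
    channels = {"hoechst": cfg["hoechst"]}
    if cfg.get("gfp"):
        channels["gfp"] = cfg["gfp"]
    used: dict[str, str] = dict(cfg)

    # --- segmentation ---
    if resume and artifacts["features"].exists():
        logger.info("segment: reusing %s", artifacts["features"])
        features = pd.read_csv(artifacts["features"])
    else:
        try:
            movie = read_movie(channels)
            sp = seg.SegmentationParams(
                method=cfg.get("segmentation_method", "seeded_growth"),
                smoothing_sigma=float(cfg.get("smoothing_sigma", 1.5)),
                min_area=int(cfg.get("min_area", 30)),
                max_area=int(cfg.get("max_area", 2000)),
                seed_min_distance=int(cfg.get("seed_min_distance", 5)),
            )
            used.update(
                segmentation_method=sp.method,
                smoothing_sigma=str(sp.smoothing_sigma),
                min_area=str(sp.min_area),
                max_area=str(sp.max_area),
            )
            gfp = movie.stack("gfp") if "gfp" in channels else None
            masks, features = seg.segment_movie(movie.stack("hoechst"), sp, gfp)
            tifffile.imwrite(artifacts["masks"], masks.astype(np.uint16),
                             photometric="minisblack")
            features.to_csv(artifacts["features"], index=False)
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage 'segment' failed on inputs {channels}: {err}"
            ) from err

    # --- tracking ---
    if resume and artifacts["tracks"].exists():
        logger.info("track: reusing %s", artifacts["tracks"])
        tracks_df = pd.read_csv(artifacts["tracks"])
        tracks = tracks_from_dataframe(tracks_df)
    else:
        try:
            frames = trk.frames_from_features(features)
            p = tracking_params_from_config(cfg)
            have_thresholds = any(k.startswith("threshold.") for k in cfg)
            if not have_thresholds:
                thresholds, gate = trk.estimate_thresholds(
                    frames,
                    percentile=float(cfg.get("threshold_percentile", 95)),
                    features=p.features,
                )
                p.thresholds.update(thresholds)
                p.distance_gate = gate
                logger.info("estimated thresholds: %s, gate %.2f", thresholds, gate)
            used.update({f"threshold.{f}": repr(p.thresholds[f]) for f in p.features})
            used["distance_gate"] = repr(p.distance_gate)
            tracks = trk.track_movie(frames, p, cfg.get("assigner", "custom"))
            tracks_df = tracks_to_dataframe(tracks, features)
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'track' failed: {err}") from err

    # --- lineage ---
    try:
        dp = lin.DivisionParams(
            drop_fraction=float(cfg.get("drop_fraction", 0.25)),
            daughter_search_radius=float(cfg.get("daughter_search_radius", 30.0)),
            min_division_score=float(cfg.get("min_division_score", 0.5)),
        )
        used.update(
            drop_fraction=str(dp.drop_fraction),
            daughter_search_radius=str(dp.daughter_search_radius),
            min_division_score=str(dp.min_division_score),
        )
        events, tracks = lin.detect_divisions(tracks, features, dp)
        forest = lin.build_lineages(tracks, events, features)
        tracks_df = tracks_to_dataframe(tracks, features)
        tracks_df.to_csv(artifacts["tracks"], index=False)
        divisions_to_dataframe(events).to_csv(artifacts["divisions"], index=False)
        forest.timecourses.to_csv(artifacts["lineages"], index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'lineage' failed: {err}") from err

    write_config(artifacts["run_log"], used)
    return artifacts
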