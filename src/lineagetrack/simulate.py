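"""Synthetic two-channel time-lapse movies with full ground truth.

Generates movies of fluorescently labelled nuclei (a DNA-stain channel plus
an optional reporter channel) whose statistics match what the tracker
assumes: gamma-distributed nucleus areas, isotropic frame-to-frame motion
with a hard displacement cap, near-conserved integrated nuclear intensity
along a track, and divisions that split the parent's integrated intensity
between two daughters with a small, controllable asymmetry.

Every movie comes with exact ground truth (label masks, centroids, the
frame-to-frame link set and the division set), so segmentation, tracking,
division detection and the evaluation metrics can all be benchmarked
without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed without overlap."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic movie.

    Defaults emulate nuclei imaged at 10x magnification: mean nucleus area
    shape*scale = 7.4 * 20.2 ~ 149 px^2 (diameter ~14 px), mean per-frame
    displacement ~4 px with a hard cap of 28 px, and integrated nuclear
    intensity conserved along a track up to a few percent of jitter.

    ``intensity_cv`` is the cell-to-cell spread of integrated intensity;
    ``intensity_jitter_cv`` is the much smaller frame-to-frame wobble of a
    single cell's integrated intensity (photon noise, focus drift).
    ``daughter_intensity_asymmetry`` is the expected absolute difference
    between the two daughters' intensities as a fraction of the parent's.
    """

    image_size: tuple[int, int] = (512, 512)  # (width, height)
    n_frames: int = 24
    initial_cell_count: int = 150
    area_gamma_shape: float = 7.4
    area_gamma_scale: float = 20.2  # px^2
    area_jitter_cv: float = 0.04
    displacement_sigma: float = 5.0  # px/frame; magnitude is half-normal
    displacement_max: float = 28.0  # px/frame, hard cap
    division_probability: float = 0.01  # per cell per frame transition
    intensity_mean: float = 20000.0
    intensity_cv: float = 0.25
    intensity_jitter_cv: float = 0.03
    daughter_intensity_asymmetry: float = 0.06
    daughter_area_fraction: float = 0.55
    gfp_fraction: float = 0.5
    gfp_intensity_mean: float = 10000.0
    gfp_intensity_cv: float = 0.5
    background_level: float = 20.0
    noise_sigma: float = 5.0
    axis_ratio_range: tuple[float, float] = (1.0, 1.8)
    min_separation_factor: float = 0.7  # of summed semi-minor axes
    confluent: bool = False  # disable the separation rejection
    seed: int = 0

    def validate(self) -> None:
        if min(self.image_size) <= 0 or self.n_frames <= 0:
            raise ValueError("image size and frame count must be positive")
        if self.initial_cell_count <= 0:
            raise ValueError("initial_cell_count must be positive")
        if not (0.0 <= self.division_probability <= 1.0):
            raise ValueError("division_probability must lie in [0, 1]")
        if not (0.0 <= self.gfp_fraction <= 1.0):
            raise ValueError("gfp_fraction must lie in [0, 1]")
        if self.displacement_max < self.displacement_sigma:
            raise ValueError("displacement_max must be >= displacement_sigma")
        if self.area_gamma_shape <= 0 or self.area_gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")


@dataclass
class GroundTruth:
    """Exact per-frame truth for a synthetic movie.

    masks
        (n_frames, H, W) uint16 label stack; labels are globally unique
        cell identities, 0 is background.
    positions
        One row per cell per frame: frame, cell_id, x, y (true continuous
        centre, 0-based, x = column), area, integrated_hoechst,
        integrated_gfp (noise-free values).
    links
        Frame-to-frame identity links: frame_t, cell_id_t, cell_id_t1,
        is_division, parent_id. A division contributes two rows (parent to
        each daughter) flagged is_division.
    divisions
        One row per division with the exact (noise-free) intensity split:
        frame (last parent frame), parent_id, daughter1_id, daughter2_id
        and the parent/daughter integrated intensities on both channels.
    """

    masks: np.ndarray
    positions: pd.DataFrame
    links: pd.DataFrame
    divisions: pd.DataFrame


@dataclass
class _Cell:
    cell_id: int
    x: float
    y: float
    area: float  # base area, px^2
    intensity: float  # base integrated nuclear intensity
    gfp: float  # base integrated reporter intensity (0 if not expressing)
    axis_ratio: float
    orientation: float  # radians


def _semi_axes(area: float, ratio: float) -> tuple[float, float]:
    # pi * a * b = area, a / b = ratio  (a = semi-major)
    b = np.sqrt(area / (np.pi * ratio))
    return ratio * b, b


def _clamp_centre(x: float, y: float, a: float, w: int, h: int) -> tuple[float, float]:
    m = a + 1.0
    return float(np.clip(x, m, w - 1 - m)), float(np.clip(y, m, h - 1 - m))


def _place_initial_cells(cfg: SimulationConfig, rng: np.random.Generator) -> list[_Cell]:
    w, h = cfg.image_size
    cells: list[_Cell] = []
    minors: list[float] = []
    max_tries = 2000
    for cid in range(1, cfg.initial_cell_count + 1):
        area = rng.gamma(cfg.area_gamma_shape, cfg.area_gamma_scale)
        ratio = rng.uniform(*cfg.axis_ratio_range)
        a, b = _semi_axes(area, ratio)
        placed = False
        for _ in range(max_tries):
            x = rng.uniform(a + 1, w - 2 - a)
            y = rng.uniform(a + 1, h - 2 - a)
            if not cfg.confluent and cells:
                xs = np.array([c.x for c in cells])
                ys = np.array([c.y for c in cells])
                dmin = cfg.min_separation_factor * (np.array(minors) + b)
                if np.any(np.hypot(xs - x, ys - y) < dmin):
                    continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {cid} of {cfg.initial_cell_count} "
                f"in a {w}x{h} image after {max_tries} tries"
            )
        intensity = cfg.intensity_mean * max(
            0.05, 1.0 + cfg.intensity_cv * rng.standard_normal()
        )
        gfp = 0.0
        if rng.uniform() < cfg.gfp_fraction:
            gfp = cfg.gfp_intensity_mean * max(
                0.05, 1.0 + cfg.gfp_intensity_cv * rng.standard_normal()
            )
        cells.append(
            _Cell(cid, x, y, area, intensity, gfp, ratio, rng.uniform(0, np.pi))
        )
        minors.append(b)
    return cells


def _render_frame(
    cells: list[_Cell],
    realized_area: dict[int, float],
    realized_int: dict[int, float],
    realized_gfp: dict[int, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, float], dict[int, float]]:
    """Rasterize one frame; returns (hoechst, gfp, labels, sums_h, sums_g)."""
    w, h = cfg.image_size
    labels = np.zeros((h, w), dtype=np.uint16)
    # contested pixels go to the nearer centre
    dist = np.full((h, w), np.inf, dtype=np.float64)
    for c in cells:
        a, b = _semi_axes(realized_area[c.cell_id], c.axis_ratio)
        x0, x1 = int(np.floor(c.x - a)), int(np.ceil(c.x + a)) + 1
        y0, y1 = int(np.floor(c.y - a)), int(np.ceil(c.y + a)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - c.x, yy - c.y
        ct, st = np.cos(c.orientation), np.sin(c.orientation)
        u = (dx * ct + dy * st) / a
        v = (-dx * st + dy * ct) / b
        inside = u * u + v * v <= 1.0
        d = dx * dx + dy * dy
        win = inside & (d < dist[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][win] = c.cell_id
        dist[y0:y1, x0:x1][win] = d[win]
    counts = np.bincount(labels.ravel())
    hoechst = np.zeros((h, w), dtype=np.float64)
    gfp = np.zeros((h, w), dtype=np.float64)
    sums_h: dict[int, float] = {}
    sums_g: dict[int, float] = {}
    for c in cells:
        n = counts[c.cell_id] if c.cell_id < len(counts) else 0
        if n == 0:  # fully occluded; keep nominal value in the tables
            sums_h[c.cell_id] = realized_int[c.cell_id]
            sums_g[c.cell_id] = realized_gfp[c.cell_id]
            continue
        region = labels == c.cell_id
        hoechst[region] = realized_int[c.cell_id] / n
        if realized_gfp[c.cell_id] > 0:
            gfp[region] = realized_gfp[c.cell_id] / n
        sums_h[c.cell_id] = realized_int[c.cell_id]
        sums_g[c.cell_id] = realized_gfp[c.cell_id]
    hoechst += cfg.background_level + cfg.noise_sigma * rng.standard_normal((h, w))
    gfp += cfg.background_level + cfg.noise_sigma * rng.standard_normal((h, w))
    hoechst = np.clip(np.rint(hoechst), 0, 65535).astype(np.uint16)
    gfp = np.clip(np.rint(gfp), 0, 65535).astype(np.uint16)
    return hoechst, gfp, labels, sums_h, sums_g


def simulate_movie(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a two-channel synthetic movie with exact ground truth.

    Returns (hoechst_stack, gfp_stack, ground_truth); the stacks are
    (n_frames, H, W) uint16. Identical configs (including seed) give
    bit-identical output.

    Nuclei are rendered as uniformly filled ellipses scaled so that the
    noise-free pixel sum equals the cell's integrated intensity, making
    intensity conservation exactly checkable. Per-frame displacement
    magnitudes are half-normal(``displacement_sigma``) capped at
    ``displacement_max`` with a uniform direction. A division replaces the
    parent by two daughters in the next frame whose integrated intensities
    sum exactly to the parent's (before noise) and whose areas are each
    ``daughter_area_fraction`` of the parent's.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.image_size
    cells = _place_initial_cells(config, rng)
    next_id = len(cells) + 1

    masks = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    hoechst_stack = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    gfp_stack = np.zeros((config.n_frames, h, w), dtype=np.uint16)
    pos_rows: list[tuple] = []
    link_rows: list[tuple] = []
    div_rows: list[tuple] = []

    for f in range(config.n_frames):
        realized_area = {
            c.cell_id: c.area * max(0.2, 1.0 + config.area_jitter_cv * rng.standard_normal())
            for c in cells
        }
        realized_int = {
            c.cell_id: c.intensity
            * max(0.05, 1.0 + config.intensity_jitter_cv * rng.standard_normal())
            for c in cells
        }
        realized_gfp = {
            c.cell_id: (
                c.gfp * max(0.05, 1.0 + config.intensity_jitter_cv * rng.standard_normal())
                if c.gfp > 0
                else 0.0
            )
            for c in cells
        }
        hoechst_stack[f], gfp_stack[f], masks[f], sums_h, sums_g = _render_frame(
            cells, realized_area, realized_int, realized_gfp, config, rng
        )
        for c in cells:
            pos_rows.append(
                (f, c.cell_id, c.x, c.y, realized_area[c.cell_id],
                 sums_h[c.cell_id], sums_g[c.cell_id])
            )

        if f == config.n_frames - 1:
            break

        new_cells: list[_Cell] = []
        for c in cells:
            if rng.uniform() < config.division_probability:
                # split the base intensity exactly; expected |d1-d2|/parent
                # equals daughter_intensity_asymmetry
                delta = config.daughter_intensity_asymmetry * np.sqrt(np.pi / 2.0) * rng.standard_normal()
                s = float(np.clip(0.5 + delta / 2.0, 0.25, 0.75))
                i1, i2 = s * c.intensity, (1.0 - s) * c.intensity
                g1, g2 = s * c.gfp, (1.0 - s) * c.gfp
                a_frac = config.daughter_area_fraction
                a1 = a_frac * c.area * max(0.3, 1.0 + 0.05 * rng.standard_normal())
                a2 = a_frac * c.area * max(0.3, 1.0 + 0.05 * rng.standard_normal())
                theta = rng.uniform(0, 2 * np.pi)
                rp = np.sqrt(c.area / np.pi)
                daughters = []
                for inten, gf, ar, sign in ((i1, g1, a1, 1.0), (i2, g2, a2, -1.0)):
                    d = 0.8 * rp + abs(rng.standard_normal()) * 3.0
                    amax, _ = _semi_axes(ar, c.axis_ratio)
                    x, y = _clamp_centre(
                        c.x + sign * d * np.cos(theta),
                        c.y + sign * d * np.sin(theta),
                        amax, w, h,
                    )
                    daughters.append(
                        _Cell(next_id, x, y, ar, inten, gf,
                              rng.uniform(*config.axis_ratio_range),
                              rng.uniform(0, np.pi))
                    )
                    next_id += 1
                d1, d2 = daughters
                div_rows.append(
                    (f, c.cell_id, d1.cell_id, d2.cell_id,
                     c.intensity, d1.intensity, d2.intensity,
                     c.gfp, d1.gfp, d2.gfp)
                )
                link_rows.append((f, c.cell_id, d1.cell_id, True, c.cell_id))
                link_rows.append((f, c.cell_id, d2.cell_id, True, c.cell_id))
                new_cells.extend(daughters)
            else:
                mag = min(
                    abs(rng.standard_normal()) * config.displacement_sigma,
                    config.displacement_max,
                )
                phi = rng.uniform(0, 2 * np.pi)
                a, _ = _semi_axes(c.area, c.axis_ratio)
                nx, ny = _clamp_centre(
                    c.x + mag * np.cos(phi), c.y + mag * np.sin(phi), a, w, h
                )
                link_rows.append((f, c.cell_id, c.cell_id, False, -1))
                new_cells.append(dataclasses.replace(c, x=nx, y=ny))
        cells = new_cells

    positions = pd.DataFrame(
        pos_rows,
        columns=["frame", "cell_id", "x", "y", "area",
                 "integrated_hoechst", "integrated_gfp"],
    )
    links = pd.DataFrame(
        link_rows,
        columns=["frame_t", "cell_id_t", "cell_id_t1", "is_division", "parent_id"],
    )
    divisions = pd.DataFrame(
        div_rows,
        columns=["frame", "parent_id", "daughter1_id", "daughter2_id",
                 "parent_intensity", "daughter1_intensity", "daughter2_intensity",
                 "parent_gfp", "daughter1_gfp", "daughter2_gfp"],
    )
    return hoechst_stack, gfp_stack, GroundTruth(masks, positions, links, divisions)


def save_simulation(
    out_dir: str | Path,
    hoechst: np.ndarray,
    gfp: np.ndarray,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a simulated movie to disk.

    Produces 16-bit multi-page TIFFs for both channels and the label masks,
    plus two CSV tables (positions and links). Coordinates are 0-based
    pixel indices, origin top-left, x = column, y = row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hoechst": out / "hoechst.tif",
        "gfp": out / "gfp.tif",
        "masks": out / "masks.tif",
        "positions": out / "positions.csv",
        "links": out / "links.csv",
        "divisions": out / "divisions.csv",
    }
    tifffile.imwrite(paths["hoechst"], hoechst, photometric="minisblack")
    tifffile.imwrite(paths["gfp"], gfp, photometric="minisblack")
    tifffile.imwrite(paths["masks"], truth.masks, photometric="minisblack")
    truth.positions.to_csv(paths["positions"], index=False)
    truth.links.to_csv(paths["links"], index=False)
    truth.divisions.to_csv(paths["divisions"], index=False)
    return paths
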