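import numpy as np
import pandas as pd
import pytest

import lineagetrack as lt


@pytest.fixture(scope="session")
def small_movie():
    """12-frame, 80-cell movie with a few divisions and full ground truth."""
    cfg = lt.SimulationConfig(
        n_frames=12, initial_cell_count=80, division_probability=0.015, seed=2
    )
    hoechst, gfp, truth = lt.simulate_movie(cfg)
    return cfg, hoechst, gfp, truth


@pytest.fixture(scope="session")
def small_features(small_movie):
    """Features measured on the ground-truth masks of the small movie."""
    cfg, hoechst, gfp, truth = small_movie
    return pd.concat(
        [
            lt.extract_features(truth.masks[f], hoechst[f], gfp[f], frame_index=f)
            for f in range(cfg.n_frames)
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def small_tracking(small_features):
    """Estimated parameters and tracks for the small movie."""
    frames = lt.frames_from_features(small_features)
    thresholds, gate = lt.estimate_thresholds(frames)
    params = lt.TrackingParameters(thresholds=thresholds, distance_gate=gate)
    tracks = lt.track_movie(frames, params)
    return frames, params, tracks


@pytest.fixture(scope="session")
def true_links(small_movie):
    """Ground-truth link set of the small movie as (frame, id_t, id_t1)."""
    _, _, _, truth = small_movie
    return {
        (int(r.frame_t), int(r.cell_id_t), int(r.cell_id_t1))
        for r in truth.links.itertuples(index=False)
    }


def draw_disk(shape=(40, 40), centre=(20, 20), radius=5.0, value=10.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    img[(yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2] = value
    return img


def draw_ellipse(img, centre, a, b, theta=0.0, value=100.0):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    dx, dy = xx - centre[1], yy - centre[0]
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    img[u * u + v * v <= 1.0] = value
    return img
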