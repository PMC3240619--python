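"""Feature selection for tracking: PCA attribution and link correlations.

Good tracking features vary widely between cells yet stay nearly constant
for one cell from frame to frame. Both properties are quantified on a
table of tracked frame-to-frame pairs: the fraction of each feature's
variance captured by the first few principal components of the
standardized feature matrix, and the squared Pearson correlation R^2 of
(value at t, value at t+1), computed separately for dividing and
non-dividing cells (division halves intensity and area, so the two
populations must not be mixed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: Static per-nucleus features considered for tracking.
ANALYSIS_FEATURES = [
    "mean_hoechst", "integrated_hoechst", "median_hoechst", "std_hoechst",
    "relative_std", "moment2", "moment2_intensity_norm",
    "moment2_area_intensity_norm", "moment2_area_norm", "area",
    "integrated_gfp", "major_axis_angle", "axis_ratio", "circularity",
]

#: Near-duplicate feature families; at most one member of each family is
#: selected for tracking (the one best captured by the leading principal
#: components), mirroring how a practitioner avoids redundant features
#: such as integrated intensity alongside mean intensity.
FEATURE_FAMILIES = [
    ["mean_hoechst", "integrated_hoechst", "median_hoechst"],
    ["std_hoechst", "relative_std"],
    ["moment2", "moment2_intensity_norm", "moment2_area_intensity_norm",
     "moment2_area_norm"],
    ["area"],
    ["integrated_gfp"],
    ["major_axis_angle"],
    ["axis_ratio"],
    ["circularity"],
]


def build_feature_table(
    features: pd.DataFrame,
    links: set[tuple[int, int, int]],
    division_links: set[tuple[int, int, int]] | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the frame-pair table underlying the feature analysis.

    ``links`` holds (frame_t, cell_id_t, cell_id_t1) tuples; rows in
    ``division_links`` are flagged ``divided``. For every feature f the
    table carries columns ``f_t``, ``f_t1`` and ``delta_f`` (t+1 minus t).
    """
    columns = columns or [c for c in ANALYSIS_FEATURES if c in features.columns]
    lookup = {
        (int(r["frame"]), int(r["cell_id"])): r for _, r in features.iterrows()
    }
    division_links = division_links or set()
    rows = []
    for frame_t, a, b in sorted(links):
        oa = lookup.get((frame_t, a))
        ob = lookup.get((frame_t + 1, b))
        if oa is None or ob is None:
            continue
        row = {"frame_t": frame_t, "cell_id_t": a, "cell_id_t1": b,
               "divided": (frame_t, a, b) in division_links}
        for c in columns:
            row[f"{c}_t"] = float(oa[c])
            row[f"{c}_t1"] = float(ob[c])
            row[f"delta_{c}"] = float(ob[c]) - float(oa[c])
        rows.append(row)
    return pd.DataFrame(rows)


def _static_columns(table: pd.DataFrame) -> list[str]:
    return [
        c[:-2]
        for c in table.columns
        if c.endswith("_t")
        and not c.startswith("delta_")
        and f"{c[:-2]}_t1" in table.columns
        and c[:-2] not in ("frame", "cell_id")
    ]


def pca_cumulative_variance(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Per-feature cumulative variance captured by the first 1..k components.

    Features (the ``*_t`` and ``delta_*`` columns of the pair table) are
    standardized to zero mean and unit variance before the decomposition,
    since they carry wildly different units. For feature i with loading
    matrix V and eigenvalues lambda, the fraction of its variance explained
    by the first m components is sum_{c<=m} lambda_c V_ic^2 (in percent,
    monotone non-decreasing in m, 100% at m = #features). Constant
    features are excluded and reported as NaN.
    """
    feat_cols = [f"{c}_t" for c in _static_columns(table)]
    feat_cols += [c for c in table.columns if c.startswith("delta_")]
    if len(table) < k + 1:
        raise ValueError("need at least k+1 rows")
    X = table[feat_cols].to_numpy(dtype=float)
    keep = np.nanstd(X, axis=0) > 0
    valid = ~np.any(np.isnan(X), axis=0) & keep
    Xv = X[:, valid]
    Xs = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    k_eff = min(k, Xs.shape[1])
    pca = PCA(n_components=Xs.shape[1])
    pca.fit(Xs)
    lam = pca.explained_variance_ * (len(Xs) - 1) / len(Xs)  # biased, matches std above
    V = pca.components_.T  # (features, components)
    contrib = lam[None, :] * V**2  # variance of each feature per component
    cum = np.cumsum(contrib, axis=1)[:, :k_eff]
    # each standardized feature has total variance 1, so the cumulative
    # explained variance is already a fraction of the feature's variance
    frac = 100.0 * cum
    out = pd.DataFrame(
        np.full((len(feat_cols), k_eff), np.nan),
        index=feat_cols,
        columns=[f"component_{i+1}" for i in range(k_eff)],
    )
    out.loc[np.array(feat_cols)[valid]] = np.minimum(frac, 100.0)
    return out


def link_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Frame-to-frame R^2 per feature, split by division status.

    Returns one row per static feature with columns ``r2_nondividing`` and
    ``r2_dividing`` (squared Pearson correlation of value at t vs t+1).
    Classes with under 3 rows or zero variance yield NaN.
    """
    feats = _static_columns(table)
    out = {}
    for label, mask in (
        ("r2_nondividing", ~table["divided"].astype(bool)),
        ("r2_dividing", table["divided"].astype(bool)),
    ):
        sub = table[mask]
        col = {}
        for f in feats:
            a = sub[f"{f}_t"].to_numpy(dtype=float)
            b = sub[f"{f}_t1"].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            if len(a) < 3 or a.std() == 0 or b.std() == 0:
                col[f] = np.nan
            else:
                col[f] = float(np.corrcoef(a, b)[0, 1] ** 2)
        out[label] = col
    return pd.DataFrame(out)


def select_features(
    variance: pd.DataFrame,
    r2: pd.DataFrame | dict[str, float],
    min_r2: float = 0.8,
    min_variance: float = 50.0,
    component: int = 3,
) -> list[str]:
    """Choose the tracking feature set.

    A feature qualifies when at least ``min_variance`` percent of its
    variance is captured by the first ``component`` principal components
    AND its non-dividing link R^2 reaches ``min_r2``; within each
    near-duplicate family only the qualifying member with the highest
    variance capture is kept. Centroid distance is always included (it is
    the one feature with perfect frame-to-frame correlation by
    construction). Deterministic and order-stable.
    """
    if isinstance(r2, pd.DataFrame):
        r2_map = r2["r2_nondividing"].to_dict()
    else:
        r2_map = dict(r2)
    if len(r2_map) == 0:
        raise ValueError("empty feature list")
    col = f"component_{component}"
    cols = [c for c in variance.columns if c.startswith("component_")]
    if col not in variance.columns and cols:
        col = cols[-1]

    def var_of(f: str) -> float:
        for key in (f, f"{f}_t"):
            if key in variance.index:
                v = variance.loc[key, col]
                return float(v) if not pd.isna(v) else -1.0
        return -1.0

    selected = ["distance"]
    for family in FEATURE_FAMILIES:
        qualifying = [
            f for f in family
            if f in r2_map
            and not pd.isna(r2_map[f])
            and r2_map[f] >= min_r2
            and var_of(f) >= min_variance
        ]
        if qualifying:
            best = max(qualifying, key=var_of)
            selected.append(best)
    # features outside the known families are judged individually
    known = {f for fam in FEATURE_FAMILIES for f in fam}
    for f in r2_map:
        if f not in known and not pd.isna(r2_map[f]) \
                and r2_map[f] >= min_r2 and var_of(f) >= min_variance:
            selected.append(f)
    return selected
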