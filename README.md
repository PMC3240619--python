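# lineagetrack

Cell-lineage tracking for high-throughput fluorescence microscopy at **low
temporal resolution**. When frames arrive every 10–30 minutes, nuclei move
by several diameters between frames, mitosis happens *between* frames, and
overlap- or motion-model trackers fail. `lineagetrack` is aimed at
experiments that follow fluorescent reporter expression through cell
divisions — e.g. Hoechst-stained nuclei plus a GFP reporter — and provides
the whole chain: nucleus segmentation, statistical frame-to-frame linking,
division detection, lineage assembly, and benchmark metrics, all
exercisable on synthetic movies with exact ground truth.

## The scoring model

Cells in frame *t* are matched to cells in frame *t+1* by a **transition
matrix** of similarity scores. For each feature *f* (centroid distance,
nuclear area, mean intensity, intensity standard deviation, area-normalized
second intensity moment) the difference *D(f)* between the two cells is
mapped through a falling logistic

```
s_f(D) = (1 + exp(-α T)) / (1 + exp(α (D − T)))
```

normalized so that *s(0) = 1*: differences below the threshold *T(f)* cost
almost nothing, differences beyond it are penalized steeply (*α* sets the
steepness, default *αT = 5*). Per-feature scores combine into one score in
[0, 1] as a weighted geometric product `Π_f s_f^w(f)` — a cell whose
position and features are unchanged scores exactly 1. Thresholds are
estimated from a high percentile (default 95th) of the feature differences
along bootstrap nearest-neighbour links; weights default to 0.9 for
position and mean intensity and 0.5 for the rest, and both can be refined
by a coordinate-wise hill climb.

Scores are computed only for pairs within a distance gate, so cost scales
linearly with cell count. Assignment is either a four-stage procedure
(mutual-best commitment, greedy completion, pairwise swap optimization) or
the Hungarian algorithm on a zero-padded square matrix.

**Divisions** betray themselves in the nuclear channel: the DNA stain
segregates into the daughters, so integrated intensity *and* nuclear area
drop by ≥25% across one transition. Candidate daughter pairs are scored by
how alike the daughters are and by how closely a *composite cell* (summed
area and intensity) matches the parent, with intensity weighted 1 and area
0.25; accepted events link tracks into lineage trees spanning multiple
generations.

## Worked example

```python
import pandas as pd
import lineagetrack as lt

cfg = lt.SimulationConfig(n_frames=12, initial_cell_count=80,
                          division_probability=0.015, seed=2)
hoechst, gfp, truth = lt.simulate_movie(cfg)

features = pd.concat(
    [lt.extract_features(truth.masks[f], hoechst[f], gfp[f], frame_index=f)
     for f in range(cfg.n_frames)], ignore_index=True)
frames = lt.frames_from_features(features)
thresholds, gate = lt.estimate_thresholds(frames, percentile=95)
print(f"estimated T(distance) = {thresholds['distance']:.1f} px, gate = {gate:.1f} px")

params = lt.TrackingParameters(thresholds=thresholds, distance_gate=gate)
tracks = lt.track_movie(frames, params, assigner="custom")
events, tracks = lt.detect_divisions(tracks, features, lt.DivisionParams())

gold = truth.positions.rename(columns={"cell_id": "track_id"})[
    ["track_id", "frame", "x", "y"]]
score = lt.tracking_accuracy(tracks, gold, match_radius=6.0, features=features)
print(f"link accuracy {score.accuracy_pct:.1f}% "
      f"({score.correct_links}/{score.total_links} links), "
      f"longest sections {score.longest_chain_pct:.1f}%")

stats = lt.division_partition_stats(
    lt.collect_division_values(events, tracks, features, "integrated_hoechst"))
print(f"{len(events)} divisions detected; daughter intensity sum "
      f"{stats.sum_pct_mean:.1f}% of parent, |difference| {stats.diff_pct_mean:.1f}%")
```

prints

```
estimated T(distance) = 10.1 px, gate = 15.5 px
link accuracy 99.3% (904/910 links), longest sections 98.4%
17 divisions detected; daughter intensity sum 102.0% of parent, |difference| 3.7%
```

The estimated distance threshold is the 95th percentile of observed
per-frame displacements; link accuracy is the fraction of ground-truth
frame-to-frame links the tracker reproduced, and "longest sections" sums
each true track's longest continuously correct stretch. The daughter
statistics confirm that integrated nuclear intensity is nearly conserved
through division and split close to 50/50.

A command-line interface covers the same pipeline:
`lineagetrack simulate | segment | track | lineage | evaluate | run`
(see `lineagetrack --help`).

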