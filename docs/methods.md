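# Methods

## Scope and model

`lineagetrack` reconstructs cell lineages from two-channel time-lapse
movies sampled at low temporal resolution (frame intervals of 10–30
minutes). The nuclear-stain channel identifies and characterises every
cell; the reporter channel is only quantified (integrated intensity per
nucleus). Three model assumptions drive everything:

1. **Feature persistence.** A cell's position changes by at most a couple
   of nucleus diameters per frame, and its nuclear features (area, mean
   intensity, intensity standard deviation, second intensity moment)
   change little between consecutive frames.
2. **Intensity conservation.** Integrated nuclear-stain intensity is
   approximately conserved along a track — DNA content does not fluctuate —
   and is inherited additively by the daughters at division.
3. **Division signature.** Across the one transition spanning mitosis,
   integrated intensity and nuclear area each drop by at least ~25%,
   because the chromatin segregates into two smaller daughter nuclei.

## Transition scoring

For cells *a* (frame *t*) and *b* (frame *t+1*) and each tracking feature
*f*, the difference `D(f)` is mapped through a normalized falling logistic

    s_f(D) = (1 + exp(-α T)) / (1 + exp(α (D − T)))

with threshold `T(f)` in the feature's units and steepness `α(f)`
(default `5/T(f)`, i.e. score ≈ 0.5 at `D = T` and ≈ 1 for `D ≪ T`, one
dimensionless shape for all features). The logistic is normalized so
`s(0) = 1` exactly. The distance pseudo-feature uses the Euclidean
centroid distance as its difference.

Per-feature scores combine as a weighted geometric product
`Π_f s_f^{w(f)}` (default), which keeps the combined score in [0, 1] and
makes an unchanged cell score exactly 1. A literal arithmetic product
`Π_f w(f)·s_f` is retained as `combine_mode="literal_product"` for
comparison; its identity score is the product of the weights (0.10125 at
the defaults), not 1, which is why the geometric form is the default.

Default features and weights: distance 0.9, mean intensity 0.9, area 0.5,
intensity standard deviation 0.5, area-normalized second moment 0.5 —
position and intensity are the two most strongly frame-to-frame correlated
features, hence the higher initial weight.

**Thresholds** are estimated per movie rather than fixed: a bootstrap pass
links cells greedily to their nearest neighbour within a generous gate
(40 px default), and `T(f)` is set to a high percentile (default 95th,
valid range 90–99) of the absolute feature differences along those links.
The distance gate is 1.2× the 99th displacement percentile. Below 50
bootstrap links the estimator falls back to documented defaults with a
warning. An optional coordinate-wise hill climb refines weights and
thresholds: each parameter is perturbed by ±1% of its range (1.0 for
weights, twice the initial value for thresholds), improvements are kept,
and the perturbation scale doubles after any full sweep without
improvement, capped at 16%, to escape shallow local optima. The objective
is either the total assigned score (no ground truth needed) or link
accuracy against a gold standard.

## Assignment

Scores are computed only for pairs within the distance gate (KD-tree range
query), so the transition matrix is sparse and cost grows linearly with
cell count. Two assigners operate on it:

* **Four-stage assignment** — (1) per-cell candidate lists of the top
  5 scores in both directions; (2) repeated commitment of links whose best
  available forward choice is also the target's best available inbound
  choice; (3) greedy completion of the remaining cells, strongest first;
  (4) pairwise swap optimization: any two committed links exchange targets
  when the summed score improves, iterated to a fixed point. The swap
  stage never decreases the frame's total score and terminates because the
  total strictly increases over finitely many matchings. Ties anywhere are
  broken by smaller centroid distance, then smaller cell id, making the
  procedure deterministic.
* **Hungarian assignment** — optimal linear assignment
  (`scipy.optimize.linear_sum_assignment`) on the score matrix zero-padded
  to square; padding entries and gated-out pairs are stripped from the
  result so they yield unmatched cells, never forced links.

The Hungarian route is provably optimal per transition; the four-stage
route is kept as the default because its structure (explicit candidate
lists, unmatched cells) feeds division detection directly. On random dense
matrices its summed assigned score stays within ~1–2% of the exhaustive
optimum in aggregate, though single adversarial instances can settle at a
2-opt local optimum around 85–90% — accepted as inherent to the pairwise
exchange design.

## Division detection and lineages

Candidate parent endpoints are track positions where integrated intensity
AND area both drop by ≥ `drop_fraction` (default 0.25) across the outgoing
transition, plus track terminations followed by at least two new tracks
starting within the daughter search radius (the parent can vanish between
frames when M-phase falls into the sampling gap). For each candidate,
daughter pairs are drawn from new-track starts within the radius (default
30 px) and the parent track's own continuation. Each pair receives

    score = sim(d1, d2) × sim(d1 + d2, parent)

where `sim` is the combined score restricted to integrated intensity
(weight 1) and area (weight 0.25), with sigmoid thresholds set to 25% of
the parent's own intensity and area. Intensity dominates because it is
conserved through division far more tightly than area (daughters are
measured mid-spreading and can jointly exceed the parent's area). A
perfect split scores exactly 1; the best pair is accepted at
`min_division_score` ≥ 0.5.

Proposals are resolved in frame order so a predicted track that chains
through several generations can be split repeatedly; within a frame,
higher scores win conflicts, and every daughter joins at most one
division. When an accepted pair includes the parent's continuation, the
parent track is split at the division frame and the tail becomes the
daughter track. Tracks plus division events form a directed forest
(validated: ≤ 1 parent, ≤ 2 children, acyclic) with per-node fluorescence
time courses.

Daughter-partition statistics summarise, per channel, the daughters' sum
and absolute difference as percentages of the parent (mean ± s.e.m.) and
the squared Pearson correlation between daughters.

## Segmentation

* **Global threshold** — Gaussian smoothing (σ = 1.5 px) then Li's
  minimum-cross-entropy threshold; 8-connected components; size filter
  30–2000 px² (nuclei at 10× are ~95–155 px²; the cuts remove debris and
  unresolvable clumps). Otsu is available behind a flag.
* **Local threshold** — mean of a moving window (radius 25 px) minus an
  offset; robust to slow illumination gradients.
* **Seeded growth** — seeds are the union of (a) local maxima of a more
  strongly smoothed image (σ = 2.5 px) above the global threshold, which
  separate touching nuclei of different brightness, and (b) local maxima
  of the foreground distance transform, which separate touching nuclei of
  similar brightness by shape (the neck between two round nuclei has a low
  distance value even when the intensity profile is flat). Seeds closer
  than `seed_min_distance` (4 px) are merged. Foreground pixels of each
  connected component go to the nearest seed within the component (ties to
  the lower seed label); components without seeds keep a single label.
  Intensity-only seeding was measured to miss ~25% of cells at 425
  cells/frame on uniformly rendered nuclei; adding shape seeds brings
  positional false negatives below 8% at 300–600 cells/frame with false
  positives below 1%.

Feature extraction measures Table-style descriptors per labelled region:
area, mean/median/std/integrated intensity, relative std, the second
intensity moment Σ I·r² about the centroid and its three normalized
variants, axis ratio and orientation from the intensity-weighted
second-moment tensor, circularity 4πA/P² with a Crofton perimeter
estimate, and integrated reporter intensity (reported absent, not zero,
when the channel is missing).

## Feature selection

On a table of tracked frame-to-frame pairs, two statistics are computed
per feature: the cumulative fraction of its variance captured by the first
*k* principal components of the standardized feature matrix (features are
standardized because their units differ by orders of magnitude), and the
squared Pearson correlation between its values at *t* and *t+1*, split
into dividing and non-dividing pairs (division halves intensity and area,
so mixing the classes would depress every correlation). A feature is
selected when ≥ 50% of its variance is captured within the first 3
components AND its non-dividing R² reaches 0.8; within each near-duplicate
family (mean/integrated/median intensity; std/relative std; the four
second-moment variants) only the member with the highest variance capture
is kept, because redundant features add weight-tuning burden without
information. Centroid distance is always included. Both cut-offs are
configuration.

## The synthetic movie generator

The generator is first-class, tested code; it emulates the statistical
structure the tracker assumes, not photorealistic microscopy:

* nucleus areas ~ Gamma(shape 7.4, scale 20.2), mean ≈ 149 px²
  (diameter ≈ 14 px at 10×);
* per-frame displacement: half-normal magnitude (σ = 5 px → mean ≈ 4 px)
  capped at 28 px, uniform direction;
* cells rendered as uniformly filled ellipses (axis ratio 1.0–1.8, random
  orientation) scaled so the noise-free pixel sum equals the cell's
  integrated intensity — conservation is exactly checkable;
* integrated intensity per cell: population CV 0.25 around 20 000, with a
  3% frame-to-frame jitter (two separate parameters: a single CV cannot
  produce both realistic cell-to-cell spread and the near-unity
  frame-to-frame correlation of integrated nuclear intensity);
* divisions (default probability 0.01 per cell per frame) replace the
  parent by two daughters whose intensities sum *exactly* to the parent's,
  split with expected absolute asymmetry 6% of the parent; daughter areas
  are each ≈ 55% of the parent's; daughters appear on opposite sides of
  the parent at roughly one nucleus radius;
* additive Gaussian read noise (σ = 5) over a background of 20; stacks are
  quantised to uint16;
* placement rejects centre pairs closer than 0.7× the summed semi-minor
  axes (a `confluent` flag disables this to emulate high-density failure
  modes). Overlapping rasterizations assign contested pixels to the nearer
  centre.

Identical configurations (including seed) give bit-identical output.

Not modelled: photobleaching, stage drift, intensity texture within the
nucleus, cell death, and out-of-focus blur. Consequently, passing
benchmarks here demonstrate correctness of the algorithms under the stated
statistical assumptions — not performance on real confluent cultures,
where segmentation errors, debris and focus drift degrade all methods.

The ground-truth `positions` table records the **true continuous centres**
used for motion, so the displacement cap is exact; mask centroids of
touching nuclei can deviate from them by up to ~2 px when a neighbour
claims contested pixels (isolated nuclei agree to sub-pixel accuracy).

## Benchmark problem sizes

The test suite and the acceptance script run entirely on generated data,
sized for a single CPU: tracking is benchmarked on 24 frames at ~150
cells/frame (~4000 links), division detection on 30 frames at a 2% per
frame division rate (~100 events), segmentation on single 512×512 frames
at 300–600 cells, and assignment optimality on 200 random matrices up to
7×7 against exhaustive search. Tracking is evaluated on features measured
from the ground-truth masks, isolating linking accuracy from segmentation
errors, in the same way manually validated segmentations underlie a
typical tracking gold standard.

## Numerical and degenerate-input conventions

* Scores are computed in double precision; the swap stage requires an
  improvement > 1e-12 to avoid cycling on ties.
* Constant images yield an empty mask with a warning; empty frames yield
  empty transition matrices; an empty movie yields an empty track list.
* Two empty masks compared pixel-wise score 1 (vacuous agreement).
* A feature missing on either cell of a pair is skipped with a warning
  rather than zeroing the score.
* Zero-variance features are reported as undefined (NaN) in correlation
  and PCA outputs, never silently dropped from the report.
* In evaluation, when two gold cells map to one predicted cell, all their
  links are scored incorrect (ambiguity is a tracking failure, not a tie
  to resolve). The "longest continuously tracked section" aggregates the
  per-gold-track longest run of correct links, summed and divided by the
  total number of gold links.
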