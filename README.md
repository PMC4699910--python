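# wormpath

Single-worm tracking and locomotory path analysis for *C. elegans*
plate recordings: segmentation of the worm from grayscale video frames,
difference-image localization with virtual camera re-centering, global
centroid-path reconstruction from the camera log, movement-feature and
search-efficiency metrics, turning-event step-length extraction, and
maximum-likelihood power-law fitting that classifies each search path as
a Lévy flight, a Brownian walk, or ballistic motion.

It is written for behavioral neuroscientists and ethologists who record
single freely crawling nematodes (typically freshly removed from food,
exploring a large agar plate at high speed with frequent turns) and want
quantitative, path-based descriptions of the search strategy.

## What it computes

**Segmentation.** Each frame is Gaussian-smoothed, thresholded against
the local neighborhood mean (a pixel is on-worm when its intensity falls
below 80% of the local average), morphologically closed with a disk
element of width 5 px, and reduced to its largest connected component.
The worm position is the body centroid

    (C_x, C_y) = ( Σ x_i / M , Σ y_i / M )

over all M body pixels. Frames with an implausible component area or
with the worm at the frame edge are flagged invalid and dropped.

**Tracking.** A reference frame grabbed after each camera move is
subtracted from the current frame; immobile dark artifacts (salt
precipitates, air bubbles) cancel exactly, and the argmax of the
smoothed difference localizes the moving worm. When the worm drifts too
far from the frame centre, a (virtual) camera move re-centres it and is
appended to a per-frame camera log.

**Path and features.** Global position = (centroid + camera offset) /
calibration (px/mm). Windowed differences at interval δ give speed,
acceleration, heading (quadrant-aware), and angular speed.

**Search metrics.** Cell occupancy O_k counts the unique 1 mm² grid
cells visited per interval τ (60 s); locality L(τ_k) = E[v_k] / O_k is
high during area-restricted local search and low during dispersal.

**Steps and walk class.** The path sampled at Δt = 1 s is partitioned at
turning events — fixes where the heading deviates by more than Θ = 40°
from the heading set out at the previous event. Step lengths S_j (chords
between consecutive events) are fitted above an estimated cutoff S_min
with the continuous power-law MLE

    α̂ = 1 + n [ Σ ln(S_j / S_min) ]⁻¹ ,

S_min chosen by minimizing the Kolmogorov–Smirnov distance between the
empirical tail and the fitted model (Clauset–Shalizi–Newman). The
exponent classifies the walk: α ≤ 1 ballistic, 1 < α ≤ 3 Lévy flight,
α > 3 Brownian.

## Worked example

Simulate a 20-minute Lévy search (Pareto step lengths, α = 2), extract
turning-event steps, and fit the tail:

```sh
$ wormpath simulate --model levy --alpha 2.0 --duration 1200 --seed 7 --out path.csv
wrote 1201 samples to path.csv
$ wormpath steps --path path.csv --theta 40 --dt 1 --out steps.csv
extracted 173 steps
$ wormpath fit --steps steps.csv --window-minutes 20
{
  "alpha": 1.938504275929981,
  "xmin": 0.3154779158033929,
  "ks_distance": 0.07109997362768594,
  "n_tail": 170,
  "n_total": 173,
  "min_step": 0.3013979865088423,
  "max_step": 80.33758814140693,
  "walk_class": "levy"
}
```

The fitted exponent 1.94 recovers the generating α = 2.0 within the
sampling error of a 170-step tail, the estimated cutoff 0.32 mm sits at
the generator's minimum segment length of 0.3 mm, and the walk is
classified `levy`: rare multi-millimetre relocations dominate the tail
(max step 80 mm against a 0.30 mm minimum).

Other entry points: `wormpath render` (synthetic frame stacks),
`wormpath track` / `segment` (frames → camera log / centroids),
`wormpath features`, `wormpath occupancy`, and `wormpath run` (full
pipeline to a report bundle; enter with `--frames` + `--camera-log` or
mid-pipeline with `--path`).

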