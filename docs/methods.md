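# Methods

This note documents the models, algorithms, parameter choices, and
numerical conventions implemented in `wormpath`, and what the synthetic
validation experiments do and do not establish.

## Segmentation (`wormpath.imaging`)

Pipeline per frame: Gaussian smoothing → adaptive threshold →
morphological closing → largest connected component → centroid.

- **Gaussian smoothing** (`sigma`, default 2 px) homogenises intensities
  on the worm body so the threshold step produces fewer interior holes.
  Border mode is `nearest`, which keeps the filter mean-preserving on
  constant regions.
- **Adaptive threshold**: a pixel is on-worm iff its intensity is below
  `threshold_ratio` (default 0.80) times the mean of the surrounding
  `window × window` box (default 25 px, roughly 2–3 worm widths at
  128 px/mm; at other magnifications scale it with the worm width). At
  the image border the mean is taken over the box/image intersection.
  Local sums use an integral image, which is exact for integer frames —
  pixels exactly on the threshold boundary never flip due to float
  rounding. The comparison is strict (`<`), so a perfectly uniform frame
  yields an empty mask.
- **Closing** uses a disk structuring element of *diameter*
  `disk_width` (default 5 px, about one worm width; the radius-2 disk).
  The mask is padded with background by the element size before
  dilation/erosion, so the border behaves as open space and closing is
  idempotent.
- **Components** are 8-connected (diagonal worm bodies stay connected);
  ties between equal-area components resolve to the first label in
  raster-scan order.
- **Validity**: the selected component must have area within
  `[min_area, max_area]` (defaults 50–5000 px², tuned to an adult worm
  at 128 px/mm) and, with `reject_border` (default on), must not touch
  the frame edge — such frames (camera-motion blur, worm at the plate
  edge) are unreliable and are flagged invalid, not interpolated.

Coordinates are x = column, y = row, origin at the top-left pixel
centre, 0-based.

## Tracking (`wormpath.tracker`)

The offline tracking loop mirrors a live re-centering tracker. A
reference frame is grabbed at start and after every camera move; the
worm is localized at the argmax of the Gaussian-smoothed difference
image, restricted (after a 20-frame warm-up *and* the first camera
move) to a crop window centred on the previous location.

- **Difference polarity** (default `dark`): the difference is
  `max(reference − current, 0)`. A dark worm entering a region makes the
  difference bright there; the ghost it leaves at its reference-time
  position would be equally bright under an absolute difference and can
  capture the argmax, so the clipped signed form is the default.
  Absolute mode is available as `polarity="abs"`.
- **Subsampling** (`rate_hz`, default 10 Hz) leaves the worm time to
  move between compared frames so it does not subtract itself out.
- **Re-centering**: when the estimate drifts beyond `recenter_frac`
  (default 25%) of the frame width/height from the centre, the camera
  offset jumps by the drift and the reference refreshes immediately.
  Camera moves are instantaneous in this offline model; motor dynamics
  are out of scope. The reference is refreshed only on camera moves.
- The camera log records the offset at *every* stream frame, so the
  global reconstruction is independent of when moves happen (verified
  by running the same world under two re-center thresholds).

The localization argmax is coarse (it often sits on the worm's leading
edge); it only steers the camera. Precise positions come from
segmentation.

## Path reconstruction and movement features (`wormpath.path`)

Global position = (centroid + camera offset) / calibration. The default
calibration of 128 px/mm corresponds to a 1280×960 sensor imaging a
~10 × 7.5 mm field. Invalid frames become gaps; features are never
computed across a gap and gaps are never interpolated.

Features at window δ (default 1 s; must be a multiple of the sampling
period): speed s_t = |Δr|/δ, acceleration a_t = Δs/δ, heading
φ_t = atan2(Δy, Δx) in degrees — the two-argument arctangent, since a
plain arctangent cannot distinguish leftward from rightward motion —
and angular speed ω_t = wrap(Δφ)/δ. All angular differences are wrapped
to (−180°, 180°] before dividing. Zero displacement leaves the heading
undefined (NaN), flagged rather than invented.

## Search metrics (`wormpath.metrics`)

Cell occupancy divides the plane into square cells (`cell_size`,
default 1 mm — about one adult worm length) anchored at the floor of the
path's minimum valid x, y (anchor is configurable; counts can shift by
a boundary cell under other anchorings). A cell is visited in interval k
(τ = 60 s) iff at least one valid sample falls inside it; visitation is
sample-based, so a cell crossed between samples without a sample
landing in it is not counted — a documented limitation acceptable at
1 s sampling and worm speeds (≤ ~0.5 mm/s, under half a cell between
samples). Per-interval counts are independent across intervals (a cell
revisited later counts again); `cumulative_unique` tracks the union.

Locality L_k = E[v_k] / O_k uses the mean of instantaneous speeds over
the interval, ignoring gap samples; intervals with no valid samples are
NaN, never zero.

## Step-length extraction (`wormpath.steps`)

The path is resampled on the grid t_i = t₀ + iΔt (Δt = 1 s) by nearest
valid sample; a grid point with no valid sample within Δt/2 is a hole,
and holes split the path into segments that are analysed independently.

Walking each segment, the first fix is turning event TE₀. At each
subsequent fix the heading of the incoming inter-sample segment φ_c is
compared with the reference heading φ_p; when |wrap(φ_c − φ_p)| > Θ
(default 40°, chosen because the head of a straight-crawling worm
swings roughly ±30°) an event is declared at the vertex where the
deviating segment begins. By default φ_p is the *outbound* heading —
the first inter-sample segment after the previous event, i.e. the
direction the step set out in; the *inbound* alternative (heading into
the previous event) is a config switch, since the definition is
genuinely ambiguous. Zero-displacement segments carry the previous
heading forward.

Steps are chords between consecutive events (S_j per the Euclidean
distance), plus a terminal step from the last event to the final
sampled fix so the partition is complete — without it, a long final
relocation would silently vanish from the tail of the distribution.
Degenerate zero-length steps are emitted, not hidden (they are dropped
later by the positive-value filter of the fit).

## Power-law fit and walk classification (`wormpath.powerlaw`)

Continuous power-law formulas throughout (step lengths are continuous
distances). The tail above x_min has density
p(S) = ((α−1)/x_min)(S/x_min)^−α and the closed-form MLE
α̂ = 1 + n [Σ ln(S_j/x_min)]⁻¹. If every tail value equals x_min the
log-sum vanishes and a `DivergentFitError` is raised rather than
returning an infinite exponent.

x_min is selected by the Clauset–Shalizi–Newman procedure: candidates
are every distinct observed positive value whose tail retains at least
`tail_floor` (default 10) points; for each, the tail is refitted and
the Kolmogorov–Smirnov distance between the empirical tail CDF and the
model CDF F(x) = 1 − (x/x_min)^(1−α) is evaluated on both sides of each
empirical jump; the minimizing candidate wins, with ties broken toward
the smaller x_min (larger tail, more statistical power). The KS
statistic is computed on CDFs — the standard form; a density-based
distance is ill-defined for continuous samples. Published "distance"
columns produced with a density-style definition are therefore not
directly comparable to this D. No goodness-of-fit bootstrap p-value is
computed.

Classification partitions the real exponent line totally and
deterministically: α ≤ 1 ballistic (not normalizable as a power law),
1 < α ≤ 3 Lévy flight (divergent variance), α > 3 Brownian. The
default analysis window restricts the fit to steps ending within the
first 20 minutes of the recording (`window_minutes`, settable to None
for the whole recording).

Known estimator behaviour: on composites whose noise and tail densities
are continuous at the knee (e.g. uniform(0,1) noise below a
Pareto(α=2, x_min=1) tail — the two densities are both 1 at the knee),
the KS objective is flat to first order below the knee and the argmin
scatters over many adjacent candidates. Absolute knee recovery is good
(x̂min concentrates within a few tenths of the truth), but grid-point-
level localisation of x̂min is not a property this estimator has, and
the validation suite records this honestly.

## Synthetic fixtures (`wormpath.synthetic`)

Trajectory models (all seeded; identical specs are bit-identical):

- `ballistic`: constant heading at constant speed.
- `brownian`: correlated random walk; per-step heading increments
  ~ N(0, `turn_sigma`·√dt) with `turn_sigma` = 60°/√s by default, which
  decorrelates the heading in about a second and produces a thin
  (Rayleigh-like) step-length tail.
- `levy`: straight relocation segments with Pareto(α, x_min) lengths
  and uniform fresh headings — clusters of short moves interspersed
  with rare long relocations. Turn angles are uniform because only the
  step-length distribution defines the walk class. The generator
  returns its true segment list for ground-truth comparisons.
- `two_phase`: high-turn (local) walk until `switch_time`, then
  low-turn (global) walk; reproduces the local-then-global signature
  (mean step length low / locality high in phase 1, reversed in
  phase 2).
- Optional reflecting `bounds` emulate the plate edge.

The renderer draws the worm as a chain of disks along a
sinusoid-perturbed centreline oriented with the instantaneous heading —
a thickened wiggling line segment, deliberately not a biomechanical
model; it is sufficient to exercise segmentation and tracking. The
background is Gaussian sensor noise around a light mean with immobile
dark artifact disks; per-frame noise derives deterministically from the
world seed and the frame index. Ground-truth blob centroids and
in-view flags are available per frame. What the renderer does *not*
emulate: postural dynamics (omega turns, reversals, coiling),
illumination gradients, vignetting, agar texture, condensation, or
compression artifacts — segmentation accuracy on real plates will be
lower than on these fixtures, and the 98% fidelity figure measured on
rendered frames bounds the idealised, not the real, case.

## Validation study conditions (`wormpath.studies`)

The closed-loop experiments use, fixed once: a 100 × 75 mm arena at
10 px/mm viewed through a 160 × 120 px tracked window, worm speed
0.3 mm/s (typical off-food young adult), 20-minute recordings, three
small dark artifacts, tracking at 4 Hz, segmentation at the 1 s
step-analysis interval, Θ = 40°, Δt = 1 s, and a 20-minute fit window.
The low magnification relative to the hardware default keeps the
simulated worm (~10 × 2.5 px) and frames small, with the segmentation
window and area bounds scaled accordingly (window 15 px, area
10–300 px²). Under these conditions the full pipeline recovers the
generating walk class (Lévy α = 2.0 vs Brownian) in 20/20 seeded runs
and reconstructs positions with median error ~0.02 mm.

## Numerical conventions and degenerate inputs

- Angle wrap: (−180°, 180°], with +180° preferred over −180°.
- Empty mask → invalid centroid, never an exception.
- Identically zero difference image → previous location returned.
- Empty occupancy intervals and windows with no steps → NaN, flagged.
- All-invalid paths, too-few steps, and all-equal tails raise typed
  errors (`InsufficientDataError`, `DivergentFitError`) that the
  pipeline reports per stage instead of crashing.
- Path CSVs are written with `%.17g` and parsed with round-trip float
  precision, so entering the pipeline mid-way from a file reproduces
  in-memory results byte-identically.
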