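# Methods

`gcflow` quantifies cytoskeletal dynamics in neuronal growth cones from
calibrated fluorescence time-lapse stacks: retrograde F-actin
treadmilling speed from kymographs, EB3 plus-end comet counts at
growth-cone necks, EB3 coverage of the growth-cone footprint, marker
(Drebrin-like) intensity over time by automatic thresholding, the
standard-score correlation statistics that tie these per-growth-cone
measurements together, and plateau/half-time fits of bulk pyrene actin
polymerization assays. Because this class of live-imaging data is
rarely deposited, the package ships a synthetic scene generator with
full ground truth, and every stage is validated by parameter recovery
rather than against archived recordings.

## Coordinate, calibration and sign conventions

Images are `T x H x W` stacks with 0-based, pixel-center `(x, y) =
(column, row)` coordinates. Spatial calibration (µm/px) and temporal
calibration (s/frame) are attached to every stack; resolution order is
explicit argument, then TIFF resolution tags / ImageJ-style metadata,
then an error — never a silent default. A `duration` at `interval`
acquisition has `floor(duration/interval) + 1` frames because the frame
at t = 0 is counted; 5 min at 2 s is 151 frames.

Line ROIs are ordered base → tip, and the kymograph distance axis grows
from the line start. Retrograde motion (toward the cell body) therefore
appears as negative slope, anterograde (EB3) motion as positive slope.
ROI interchange is plain JSON rather than the binary ImageJ ROI format,
with width defaulting to 1 px.

## Kymograph velocimetry

`make_kymograph` samples the stack at unit arc-length steps along the
ROI (bilinear interpolation; nearest-neighbor behind a flag for
bit-exact toy cases), averaging across the perpendicular width when
width > 1. Sample spacing equals the pixel size.

Two speed estimators coexist:

* **Manual endpoints** — slope per clicked pair, `Δdistance/Δtime`, mean
  of |slope| converted to µm/min. This is exact arithmetic with no
  detection step and serves as the arbitration oracle.
* **Automatic** — a shear-projection orientation scan over a 1° angular
  grid (0–80°, restricted to the requested direction's sign, slopes
  capped at 5 px/frame) finds the dominant track orientation; the score
  is the column-count-weighted variance of the sheared row-mean profile.
  Weighting by the number of in-canvas columns keeps the white-noise
  contribution to the score independent of the shear, so steep and
  shallow candidate slopes compete on signal alignment alone. The peak
  is refined by parabolic interpolation in angle, then each profile peak
  (prominence above 3 robust MADs) seeds a track that is iteratively
  refit: a ±2-px band is re-centered on the current line, per-frame
  intensity centroids are computed, and a least-squares line through the
  centroids updates the slope (3 iterations). Columns whose predicted
  position lies within the band half-width of the kymograph border are
  dropped, because their clipped centroids would bias slopes toward
  zero. Tracks shorter than 5 frames or 3 distance samples are
  discarded as noise-dominated.

When no structure stands above the noise floor (99th percentile within
3 MADs of the median) the estimate is returned flagged with
`n_tracks = 0` and NaN speed — never a silent zero. On synthetic
kymographs at 1–6 µm/min (0.1 µm/px, 2 s/frame, SNR 5) the mean
estimate is within ~2% of truth; the manual mode recovers configured
slopes exactly from true endpoints.

## Comet counting

Comets crossing a counting line drawn across the neurite at the
growth-cone neck appear as compact spots in the distance × time
kymograph. Detection: difference-of-Gaussians band-pass (σ = 1 and
3 px), local maxima above `prominence × noise` where the noise level is
the MAD of frame-to-frame differences (static structure cancels and the
sparse moving spots barely move the median) propagated through the DoG
filter analytically. Default prominence is 5. Maxima closer than
(2 px, 2 frames) merge into one detection so an oscillating comet is
counted once. All thresholds are data-relative, making counts invariant
to global intensity scaling, and an all-zero kymograph counts zero
without erroring.

Ground truth for the recovery study merges crossings closer than the
fixture's spatiotemporal resolution (3 px, 3 frames) before matching:
two comets arriving simultaneously at the same lateral position render
as one spot, and a "distinct spots" counter cannot and should not
separate them. The counting-line fixture is drawn deliberately wide
(96 samples) so that such collisions stay rare even at 8 comets/min.

## Coverage

Both channels are max-projected over time; each projection is
thresholded inside the growth-cone outline (Otsu per channel by
default — parameter-free and scale-invariant; the mean auto-threshold
is available by flag since the original procedure's thresholding method
is not recorded), and the report is
`100 · |EB3 mask ∩ reference mask| / |reference mask|`. An empty
reference mask is an error, not a 0/0.

## Growth-cone intensity tracing

The automated trace emulates a per-frame "mean" auto-threshold: pixels
strictly brighter than the crop mean. Strict inequality means a
constant crop yields an empty mask (flagged degenerate) rather than a
full one — a constant crop contains no growth cone. The exact
arithmetic mean of the crop is the cutoff (ImageJ computes some means
from a 256-bin histogram; the difference is below half a gray level and
the exact mean is canonical here). By default only the largest
8-connected component is kept so stray speckles do not join the cone;
this is toggleable. Mean intensity per frame is read from the
*original* measurement channel at the mask coordinates, never from the
thresholded image. Degenerate frames are excluded from the summary mean
and reported; more than 50% degenerate frames aborts. Manual polygon
measurement uses an even-odd point-in-polygon test on pixel centers.

## Statistics

Paired per-growth-cone measurements are standard-score normalized
(sample sd, n−1) so both axes are in σ units; Pearson's r comes with a
two-sided p from the t distribution (n−2 df) and an ordinary
least-squares line. On z-scored input the slope equals r and the
intercept is 0 to 1e−9 — the identity behind reporting one number as
both the line slope and r.

Linearity is tested by a nested-model F-test (quadratic vs linear) at
α = 0.05 — the original analysis names no specific linearity test, and
the nested F is objective, reproducible, and matches the observed
linear → second-order-polynomial escalation. When significant, the
quadratic fit is reported with its R² plus a quadratic-vs-cubic
deviation-from-model check (expected non-significant). Group
comparisons: two-tailed Student's t for two groups; one-way ANOVA with
Dunnett-vs-control or Tukey all-pairs otherwise (critical values from
scipy's multivariate-t machinery); a two-way layout with interaction
plus Tukey on the cells is provided for factorial designs. Means ± SEM
(sd/√n) are reported throughout, and with exactly two groups every
post hoc reduces to the t-test. Null calibration over 1000 simulations
puts each test's empirical type-I error within [0.03, 0.07] at nominal
0.05.

Two printed slope/r pairs in the source analyses disagree slightly
despite z-scoring (a normalization variant that is not recorded); the
package does not attempt to reproduce that discrepancy and demonstrates
the identity on data where it holds exactly.

## Kinetics

Pyrene traces are fitted to a lagged single-exponential saturation
`y = y0` for `t < lag`, `y0 + (ymax−y0)(1 − e^{−k(t−lag)})` after, with
`t½ = lag + ln2/k`; the fitted curve passes through `(t½, (y0+ymax)/2)`
by construction. The fitting software behind the original numbers is
not recorded; this model reflects pyrene-assay phenomenology — a
nucleation lag followed by pseudo-first-order elongation — and the
pre-polymerization baseline cycles are absorbed by the lag parameter
rather than trimmed (trimming available by flag). Optimization is
bounded least squares, multistarted from model-free estimates (smoothed
top-decile plateau; baseline from the lowest ~2% of samples, since a
bottom *decile* reaches into the rise and biases t½ late; first
midpoint crossing, linearly interpolated). Both the fitted plateau and
the observed maximum are reported because either convention may lie
behind a published "Ymax". Flat traces (range below 5× a
difference-based noise estimate) and non-convergence raise errors.
Recovery at 2% noise: median error ~0.3% (plateau) and ~1% (half-time).

A preset table of per-condition plateau/half-time means (actin alone
down to actin + microtubules + EB3 + phospho-mimetic drebrin) generates
realistic replicate sets; `compare_ymax` sends them to Dunnett against
the actin-alone control.

## Synthetic scenes: what they emulate and what they do not

The generator renders straight-shaft neurites with disk growth cones:
F-actin speckles with Poisson turnover advect tip→base at the
configured µm/min; EB3 comets are born at the neck at a Poisson rate
and travel tipward until the tip or an exponential lifetime ends them
(a comet born at the neck counts as entered by construction, so
realized counts are exactly Poisson); the marker channel fills the
growth-cone footprint. Everything is splatted at sub-pixel positions,
blurred with a Gaussian PSF (σ = 1 px default), and corrupted by
Poisson(scale·signal)/scale plus Gaussian noise; either noise term can
be disabled. Identical config + seed gives bit-identical stacks.

Default calibration is 0.16 µm/px — plausible for a 60×/1.4 NA camera
setup, but the original acquisitions' pixel size is not recorded, so it
is a free parameter and all speed arithmetic reads calibration from
metadata rather than assuming it. Default acquisition 300 s at 2 s
(151 frames). Growth-cone and kinetic-trace defaults follow the
physiological ranges above (flow 0.3–6 µm/min, comet rates of a few per
minute, half-times of a few hundred seconds).

Deliberately absent: curved or branching neurites, photobleaching,
spectral bleed-through, 3-D optics, focus drift, comet shape anisotropy,
and growth-cone morphology change over time. Passing recovery tests
therefore demonstrates correctness of the measurement chain under the
model's assumptions (linear motion, additive noise, static geometry),
not robustness to every artifact of real microscopy; the manual
estimator and the flagged failure modes are the designed escape hatches
when the automatic assumptions break on real data.

## Problem sizes of the standard studies

Speed: 6 speeds × 20 seeds, 100×151 kymographs, 3 tracks each. Comets:
4 rates × 50 seeds, 96×151 kymographs. Coverage: 2 fractions × 10
seeds. Intensity: 5 two-neurite cells, 151 frames. Type-I: 1000 null
simulations, 3 groups of 8 (Pearson on n = 16). Kinetics: 50 traces,
181 samples each. Pipeline: 20 five-neurite cells, 151 frames,
~70×230 px. These sizes give sub-percent Monte-Carlo error on the
summary statistics while keeping a full validation run in minutes on
one core.

## Known limitations

* The automatic slope estimator assumes straight constant-velocity
  tracks; curved or accelerating trajectories are out of scope (use
  manual endpoints).
* Comet counting saturates when the counting line is short and the rate
  high (collisions are physically unresolvable); counts remain monotone
  in the true rate, which is what the correlation analyses consume.
* The "mean" threshold is global per crop; touching growth cones are
  not separated (no multi-object tracking).
* Dunnett/Tukey assume equal-variance normal groups, as in the original
  analyses; no robust or nonparametric alternatives are provided.
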