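# Methods

## Viewing geometry and the accuracy measure

All angular quantities assume a single cyclopean eye located on the
perpendicular through the display center at distance `d` (mm). Screen
positions are expressed in pixels with the origin at the display center,
+x right, +y up, and converted to mm by the display pixel pitch `µ`
(mm/px). For a point `(x, y)` mm:

* yaw = atan(x/d), pitch = atan(y/d) — signed component angles;
* primary angle = atan(√(x²+y²)/d) — total eccentricity from the screen
  normal, always ≥ 0. The identity tan²(primary) = tan²(yaw) +
  tan²(pitch) holds per construction and is asserted for every processed
  row in the tests.

Gaze angular accuracy (`DIFF GZ`) is the absolute difference of the
ground-truth and estimated primary angles. This measure is deliberately
direction-insensitive: two points at equal eccentricity on opposite
sides of the center have `DIFF GZ = 0`. Users who need a
direction-sensitive error can use `geometry.angle_between_3d`, the angle
between the two 3-D gaze vectors. The difference is not signed; the
per-condition summary tables report positive means, which is only
consistent with the absolute value.

Gaze estimates may fall off screen (trackers extrapolate); ground-truth
stimulus positions may not, and the strict reader rejects such files.
The data model is monocular — binocular recordings should be averaged to
a single gaze point upstream.

## File formats

The processed format is fixed at 21 columns with exact header names
(`TIM REL` … `STD ERR`); writers emit them byte-identically and readers
reject any deviation, so files round-trip losslessly (numerically to
1e-9). The raw format carries per-sample gaze/ground-truth pixel
coordinates plus the display resolution, pixel pitch and user distance
repeated on every row, making each file self-describing; the reader
takes metadata from the first data row. The exact column layout of the
raw dialect (TIME_MS, XRAW, YRAW, GTX, GTY, RES_X, RES_Y, PIX_PITCH,
USER_DIST) is this package's documented convention. User identity,
condition and platform are encoded in the `usNN_CONDITION_PLATFORM.csv`
file name (two-digit user numbers, hence ids 1–99); the sampling rate is
inferred from the median timestamp increment. `USER_DIST` is stored in
mm. Any non-numeric or missing cell is a validation error that names the
offending rows.

Per-stimulus aggregates (`MEAN_ERR`, `STD ERR`) use the sample (n−1)
standard deviation; a single-sample stimulus gets SD 0. Stimulus indices
(`AOI`) count *runs* of constant ground truth in time order, so a
revisited location gets a fresh index — this matches a moving-dot
protocol where episodes, not unique positions, are the unit.

## Outlier handling

Three strategies, all translation-invariant (MAD and IQR also
scale-invariant), all exposed as parameters:

* median filter: 1-D running median, window 5 by default, replicate
  padding at the edges; as a detector, samples whose residual from the
  filtered series exceeds 3 scaled MADs of the residuals are flagged;
* MAD rule: flag `|x − median| > k · 1.4826 · MAD`, default `k = 3`; the
  1.4826 factor makes the MAD a consistent σ estimate under normality. A
  zero MAD flags nothing (the alternative — flagging everything off the
  median — discards data catastrophically on quantized series);
* IQR rule: Tukey fences at `Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`, quartiles by
  linear interpolation between order statistics. The quantile convention
  matters for reproducing summary tables and is fixed to the dominant
  scientific-stack default.

None of these constants is externally prescribed; they are the standard
conventions and are configurable. Session-level removal judges rows on
`DIFF GZ`, drops flagged rows, recomputes per-stimulus aggregates on the
survivors, and refuses to empty a session. Summary statistics can be
computed before or after removal; both paths are supported since
published per-condition tables do not state which was used.

## Statistics

Summaries report mean, sample SD, **raw** (unscaled) MAD, IQR, and a 95%
normal-approximation CI (`mean ± 1.96·s/√n`; sessions have thousands of
samples). The raw MAD is the right companion to published tables: on
heavy-tailed gaze error a raw MAD can exceed the mean, which a scaled
MAD would obscure. A seeded percentile bootstrap (10 000 resamples) is
available where the normal approximation is in doubt. Z-scores of a
zero-variance series are defined as 0. Per-condition tables pool all
samples of a condition across users; per-user aggregation can be built
from the same primitives if needed.

## Similarity and distribution numerics

Histograms for comparison share equal-width edges spanning the pooled
range and are normalized to probability vectors; the default 32 bins is
a package choice. The Bhattacharyya distance is reported in the bounded
Hellinger-affine form √(1 − BC) — 0 for identical, 1 for disjoint —
computed as ½Σ(√pᵢ−√qᵢ)², which is algebraically identical but exactly
zero for identical histograms instead of accumulating rounding; the raw
coefficient BC is also exposed. Pearson correlation of a perfectly flat
probability vector is undefined; it is defined here as 1 for equal
vectors and 0 otherwise.

The error-distribution KDE uses a Gaussian kernel with the bandwidth
fixed in degrees (default 0.2°), evaluated directly from its definition
on a grid spanning the data ± 4 bandwidths, rather than through a
covariance-rescaled library estimator, so the bandwidth means exactly
what the number says. Error surfaces partition the screen (default 8×5
cells) or the yaw/pitch angle plane and report the mean error per cell;
empty cells are NaN, never 0 — an empty cell is absence of evidence, not
zero error. Cell counts conserve the sample count. 2-D point densities
use a Gaussian KDE with Scott bandwidth. Rendering is strictly separated
from these numerics: plots are drawn from, and serialized alongside as
CSV sidecars of, already-computed structures, and no test requires a
display.

## Augmentation

Seven methods synthesize variants of a gaze series: white noise, colored
noise, linear interpolation, circular time-shift, raised-cosine
convolution, and the two combinations noise+shift and noise+convolve
(the combinations are counted as methods in their own right). Colored
noise is generated by FFT-shaping white noise to a 1/f^α spectrum
(α = 1, pink, by default — a natural choice for slow drift-like
disturbances) and rescaling to the requested SD exactly. The convolution
kernel is a strictly positive raised-cosine window normalized to unit
sum; being symmetric it reproduces affine series exactly away from the
edges. Augmentation targets the estimated yaw/pitch series by default
(pixel coordinates optionally) and always rebuilds the full processed
session through the geometry, so angles, errors and aggregates stay
mutually consistent; provenance (method, parameters, seed) is encoded in
a file-name suffix. Identical seeds give identical outputs.

## Synthetic benchmark sessions

The generator emulates a fixation-protocol benchmark: a dot dwells 3 s
at each of 15 locations (a 5×3 grid inside 10% margins — odd×odd, so
the display center is itself a target) on desktop 1680×1050, laptop
1366×768 or tablet 1920×800 displays, whose pixel pitches (0.28206,
0.226917, 0.123337 mm) follow from their physical diagonals. The
sampling rate defaults to 60 Hz (a typical consumer-tracker rate; it is
configurable), giving 2700 samples per session. Dot-transition samples
are omitted by default and available behind a flag.

Per session, the error model displaces gaze in yaw/pitch angle space by
a bias of fixed magnitude and per-session random direction (emulating
calibration drift), adds isotropic Gaussian noise (σ = 0.5°), and with
probability 0.02 throws a sample an additional 20° in a random direction
(blinks/track losses). Displacements are applied in angle space and
mapped back to pixels, so injected magnitudes are exact in degrees.

Condition presets ("50"–"80" cm user distances; R20/Y20/P20 poses, with
pose sessions at the 60 cm reference distance) carry bias magnitudes
calibrated once, by bisection against the Monte-Carlo reference, so that
the *cleaned pooled* mean error per condition emulates the magnitudes
published for the real desktop and tablet benchmarks (e.g. ≈3.4° at
50 cm vs ≈1.0° at 80 cm on desktop, largest under head yaw on desktop
and platform roll on tablet). These presets are an emulation of
magnitudes and orderings only: the generator does not reproduce
physiological eye movement (microsaccades, drift spectra), anisotropic
or spatially varying bias, pupil or blink dynamics, or inter-user
variability beyond the random bias direction. Tests passing on this
model therefore validate the *pipeline arithmetic*, not any claim about
human gaze data.

The Monte-Carlo reference (`mc_reference_mean`) recomputes the expected
post-cleaning pooled mean independently of the pipeline: it re-simulates
the displacement model (conditioned on the sessions' realized bias
directions, at 10× the noise samples), obtains primary angles through
explicit 3-D vectors (atan2 of cross/dot products), and trims with Tukey
fences built on a hand-rolled sorted-order-statistic quantile. Because a
spike's effect on `DIFF GZ` depends on its direction relative to the
target's radial direction, a tangential spike is invisible in `DIFF GZ`;
reference and pipeline apply the same trimming rule so both estimate the
same population quantity. The spike-recovery test instead detects on the
radial error magnitude √(yaw_err² + pitch_err²), where injected spikes
are separable from the bulk at moderate bias.

## Problem sizes and numerical choices

The test suite and the acceptance script use 20 simulated users × 2700
samples per condition (the benchmark's own scale) with a 10× Monte-Carlo
reference; at these sizes the recovery error is ~0.01°, an order below
the 0.05° assertion. Geometry is validated against the vector oracle to
1e-9 degrees on 10⁵ random points. Round-trip equality is asserted to
1e-9; histogram probability sums to 1e-9; degenerate inputs (zero
variance, zero MAD, empty sessions, all-flagged sessions, degenerate
histogram ranges, collinear point clouds) are defined errors or defined
fallbacks as described above, never silent NaNs.

## Known limitations

* The cyclopean on-axis eye is an idealization; real head positions are
  off-axis and binocular, and no head-pose compensation is modelled.
* `DIFF GZ` is insensitive to tangential error components by
  construction (it compares eccentricities); use the 3-D angle output
  when that matters.
* The synthetic presets emulate published per-condition magnitudes, not
  the spatial or temporal structure of real tracker error; conclusions
  about real devices require real recordings.
* Reproducing the published per-condition benchmark tables exactly
  requires the deposited human dataset, which must be obtained
  separately and placed under `data/NUIG_EyeGaze01`; the corresponding
  end-to-end test fails in its absence.
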