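# Methods

## Problem and scope

`diamotion` quantifies diaphragmatic motion from a dynamic (cine)
single-slice sagittal thoracic MR series acquired during instructed
deep breathing. From every frame it extracts six measures:

* **CSA** — lung cross-sectional area inside the segmented contour (cm²);
* **ANT, CNT, PST** — 1-D cranio-caudal lung lengths at the anterior
  chest-wall margin, the carina (tracheal bifurcation) column and the
  posterior chest-wall margin (mm);
* **TDM = ANT + CNT + PST** — total distance of motion of the
  diaphragm (mm);
* **DIA** — diaphragm length: the arc over the diaphragmatic dome
  between the chest-wall margins plus the two zones of apposition, the
  segments lying flush against the chest wall below the dome (mm).

From the temporal profiles it derives per-series summary measures
(min, max, delta = max − min, mean, sample SD of each measure) and
ordinary least-squares regressions of each length against CSA over the
respiratory cycle (slope *S*, intercept *C*, signed correlation *R*,
two-sided *p* on the slope with *n* − 2 df). Cohort-level longitudinal
or mixed-effects modelling is deliberately out of scope: the package
exports tidy per-series CSV tables for external statistics software.

The single manual input is a set of three landmark points on one
reference frame (anterior margin, carina, posterior margin), supplied
as a JSON file rather than interactive clicks so that analyses are
scriptable and observer-variability experiments can be automated.

## Segmentation

The lung is dark on bright tissue in gradient-echo cine frames. Each
frame is thresholded with Otsu's method; on the reference frame the
below-threshold 4-connected component containing the landmark centroid
is kept, and on every other frame — visited in temporal order outward
from the reference — the component with maximal pixel overlap against
the previously accepted mask. Masks are regularized by a 3×3
morphological closing and hole filling, so each accepted mask is a
single 4-connected, hole-free region. A frame whose regularized mask
has Dice < 0.5 against the previous accepted mask is flagged invalid
and excluded from all downstream statistics (never interpolated); more
than 20% invalid frames aborts with "tracking lost". All of these
choices (polarity, threshold rule, connectivity, kernel, acceptance
Dice, abort fraction) are plain config keys; none is data-adaptive
beyond the per-frame Otsu threshold. The propagation is deterministic
and, on clean data, symmetric under time reversal.

## Measures: numerical choices

* Column lengths use the inclusive pixel extent
  `(bottom − top + 1) × spacing`; the +1 makes a one-pixel lung have
  nonzero length. The measurement columns are the landmark columns,
  held fixed across frames (the chest wall is static in a supine
  subject).
* The diaphragm attachment points are, per margin column, the deepest
  (most inferior) boundary row over all valid frames of the series —
  not the single max-CSA frame — which guarantees nonnegative
  apposition lengths on every frame even if the two margins peak on
  different frames.
* DIA = dome arc + both appositions. The dome is the polyline through
  the bottom-most boundary pixel per column between the margins, with
  chord vertices every 3 columns (endpoints always kept). Per-column
  chords over a pixel-quantized boundary systematically *overestimate*
  arc length wherever the local slope is fractional (for slope 0.5
  px/px the staircase reads 1.207 px per column against a true 1.118);
  at 2 mm resolution this bias reaches ~6% of the dome. The 3-column
  chord step suppresses it below the small curvature underestimate it
  trades against: on the noiseless control phantom the measured DIA is
  within 1.3% of the analytic arc, and a rasterized semicircle of
  radius 100 mm reads within 1% of π·100 mm.
* Summary SD is the sample (n − 1) standard deviation. Temporal
  profiles are never smoothed and extrema are single-frame values.
* Regression *R* is reported signed — DIA typically *falls* as CSA
  rises (the appositions shorten faster than the dome lengthens), so
  its R is strongly negative; an `abs_r` column is provided for
  comparison with conventions that report magnitudes.

## The breathing phantom

The synthetic generator renders a sagittal right-lung cross-section:
a flat apex row, vertical chest-wall margins, and an inferior boundary
(the diaphragm) that is a parabola through three control points at the
anterior margin, the carina column and the posterior margin. Each
control length follows a raised cosine starting at end-expiration,
`L(t) = Lmin + (Lmax − Lmin)(1 − cos(2πft + φ))/2`, with per-point
phase lags φ available to create regional dyssynchrony. Defaults
emulate the acquisition the pipeline targets: 2.0 mm isotropic pixels,
60 frames at 0.5 s/frame, and f = 0.1 Hz so the series spans three
deep breaths. The `control` and `dmd` presets program Lmin/Lmax from
published baseline group means of the respective cohorts (e.g. control
ANT 172.6→211.0 mm, CNT 146.2→217.3 mm, PST 182.6→258.0 mm), so the
programmed length deltas equal the published per-measure deltas by
construction.

Because the carina column is constrained to the midpoint of the
margins, Simpson's rule is exact for the parabolic boundary and the
truth CSA has the closed form `width/6 · (L_ant + 4·L_cnt + L_pst)`
(267.64 cm² at the control peak). Truth length/DIA/CSA profiles are
computed analytically from the waveforms — never from the raster — so
they are an independent oracle for the pipeline. Pixels are lung when
their center lies inside the dome; intensities are two-valued (lung
30, tissue 200, arbitrary units) plus additive zero-mean Gaussian
noise from a seeded generator. Gaussian (rather than Rician) noise is
a simplification that is adequate at magnitude-image SNRs far from the
noise floor and is trivially invertible in tests.

What the phantom does *not* emulate — and hence what passing tests do
not show about real data: cardiac motion and pulsatility, bias fields
and coil shading, rib shadows, through-plane motion, partial-volume
gradients at the lung periphery, irregular or non-sinusoidal breathing
waveforms, and (important for DIA, below) the near-vertical course of
the diaphragm where it meets the chest wall.

## Desk-scale experiments

*Synchrony.* With equal phase lags all truth lengths are affine in
truth CSA, so pipeline regressions give R ≥ 0.99 for ANT/CNT/PST/TDM;
an anterior phase lag of π/5 drops R(ANT) by ≈ 0.16. This reproduces
the mechanism of regional dyssynchrony as a loss of length-vs-CSA
linearity, at desk scale only — cohort contrasts require patient data.

*Observer variability.* Two simulated observers each re-place the
landmarks five times on three phantom subjects (control, DMD and an
intermediate geometry), after which the deterministic pipeline is
rerun — so all run-to-run variation comes from the landmarks, as in
the real protocol. Jitter is ±2 px uniform on rows and on the carina
column; the margin-landmark columns jitter inward only, because the
phantom's lung ends exactly at the margin column and an outward click
falls off the lung and is rejected rather than absorbed. %CV
(100·SD/mean over repeats) is computed per observer × subject for the
four minimum lengths, and the pooled %CV distributions of the two
observers are compared with a two-sided rank-sum test.

A known limitation: the phantom's parabolic dome meets the margin
columns at a local slope near 1 px/px, so a 2 px inward margin jitter
removes several millimetres of dome arc from min DIA with no
compensating apposition at end-inspiration. Min-DIA %CV therefore
reaches ~2.5–4% on the phantom, whereas the minimum 1-D lengths stay
below ~2%. In real anatomy the diaphragm turns near-vertical at the
chest wall (the zone of apposition), which makes DIA insensitive to
small margin-column error; the parabola phantom lacks that feature, so
its DIA jitter sensitivity overstates what the method shows on real
images.

*Group percentages.* `percent_smaller(ref, grp) = 100·(1 − grp/ref)`
applied to published baseline group means of max CSA, delta CSA and
max TDM gives 44.98%, 40.84% and 37.26% — the worked examples behind
the reported ≈45/40/37% group reductions.

## Statistics

`linear_fit` and `pearson` are direct normal-equation implementations
with *p* from the t transform on *n* − 2 df (slope-t and correlation-t
coincide for simple regression); both are cross-checked against
independent library implementations in the test suite.
`group_compare` fits `value ~ group (+ covariate)` by OLS and reports
the group term; with no covariate this is exactly the pooled-variance
two-sample t-test (pooled, not Welch, chosen as the classical
reduction). `rank_sum_exact` enumerates all C(n+m, n) rank
assignments when n + m ≤ 16 and the pooled sample is tie-free; its
two-sided *p* counts both tails mirrored about the null mean, which
reduces to twice the one-tail probability by symmetry. Larger or tied
samples use the continuity-corrected normal approximation with
midranks and tie-corrected variance; the mode used is recorded in the
result. No multiple-comparison correction is applied anywhere.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline on 60-frame
160×100 phantoms (sub-second per fit) and a 30-run observer study;
every random draw flows from an explicit integer seed, and the
pipeline itself contains no randomness, so identical inputs yield
byte-identical output tables.

## Degenerate inputs

Uniform frames have no Otsu foreground and raise a seed error (on the
reference frame) or are flagged invalid (during propagation). Empty
measurement columns, contours missing a margin column, or empty masks
yield NaN and an invalid frame rather than a crash; fewer than two
valid frames, an empty reference mask, rank-deficient comparison
designs, constant regressors and tied exact rank-sum inputs raise
errors that name the offending condition.
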