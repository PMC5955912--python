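# Methods

This note documents the models, conventions and design choices behind
`olrkit`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
details that a user re-implementing or auditing the pipeline would need.

## 1. The assay

A head-fixed mouse runs on an air-suspended Styrofoam ball at the center
of a projection dome (112 cm inner diameter).  The stimulus window spans
220° of azimuth and −10°…80° of elevation.  Random dot patterns appear
static for 1 or 2 s (interleaved, to prevent anticipation), drift left or
right in yaw for 2 s, and stand still for a final second.  The ball's yaw
is recorded at 60 Hz; because the head is fixed, the animal's reflexive
following of the pattern appears as ball rotation.  Positive yaw in this
package always means "turning with the stimulus" — a rig export in raw
ball coordinates (which rotates opposite to the animal) should be negated
once at ingest.

## 2. Stimulus geometry

* **Isotropic dot sampling.**  Azimuth is uniform over the window;
  elevation is `ele = arcsin(U(sin ele_min, sin ele_max))` (in degrees).
  The arcsine transform makes density uniform per unit solid angle;
  without it dots would crowd toward the zenith.
* **Coverage rule.**  Dot count is `round(c · Ω_win / Ω_dot)` with
  `Ω_win = Δazi_rad · (sin ele_max − sin ele_min)` ≈ 4.448 sr for the
  default window and `Ω_dot = 2π(1 − cos r)` (spherical cap; the planar
  `πr²` differs by <0.1% at these radii but the cap form is the one
  consistent with spherical coordinates).  At 27% coverage this gives
  640 dots of 1.4° radius; realized coverage stays within 0.5 percentage
  points of 27% for all five radii used (0.6, 0.9, 1.4, 2.3, 3.7°).
  Whether a real implementation counts dot area spherically or planarly
  is not observable at this precision.
* **Motion.**  Yaw motion increments all azimuths by `speed·dt` per
  frame.  Dots leaving the azimuth window re-enter at the opposite edge;
  this wrap keeps dot count, density and hence mean luminance constant
  during motion.  Elevations never change.
* **Projection LUT.**  Calibration measures the dome coordinates of
  dots projected on a 20×10 raster evenly spaced in projector pixels
  (200 nodes).  Queries go (azi, ele) → (x, y): the enclosing grid cell
  is located (monotonicity of azi along columns and ele along rows is
  validated at construction), and the cell's forward bilinear map is
  inverted by a 2×2 Newton iteration.  This is exact at the nodes and
  exact everywhere for affine dome models; on a smooth synthetic dome
  model the round-trip error is well below 0.5° everywhere inside the
  grid.  Queries outside every cell raise an error rather than
  extrapolate.
* **Component dots.**  Each displayed "dot" is 21 partially overlapping
  component dots in three concentric rings of 6, 7 and 8 around the dot
  center, at radii r/3, 2r/3 and 0.95r, each ring evenly spaced starting
  at angle 0.  The exact ring radii/counts of the original rig are not
  documented; this choice is deterministic, symmetric and gap-free given
  the finite extent of the rendered primitives.  Each component position
  is meant to be fed through the LUT individually, which is what keeps
  dots round on the curved screen.

## 3. Experiment design

Three condition grids: `speed` (9 speeds 0–72 deg/s in steps of 9 × 2
directions × 2 onsets = 36 conditions), `contrast` and `dotsize`
(5 speeds {0, 18, 36, 54, 72} × 2 × 2 × 5 factor levels = 100
conditions).  The zero-speed condition is a member of every grid — its
response curve is the reference subtracted from all motion conditions —
and both direction labels are kept for it as distinct conditions, which
is what makes the printed condition counts come out.  Sessions are
randomly interleaved block designs: each repeat is a fresh permutation of
the full condition set, with no constraint across block boundaries.
Session plans (10 repeats × 7 sessions for speed; 5 × 14 for the surface
experiments) give 70 presentations per condition either way.

Contrast conditions are parameterized by dot luminance on a fixed
0.09 cd/m² background.  The five printed two-decimal contrast labels
(0.09 … 0.95) are attached as metadata rather than recomputed at run
time: recomputing the Michelson contrast `(Lmax−Lmin)/(Lmax+Lmin)` from
the luminances as printed (themselves rounded) reproduces the labels only
to their own two-decimal precision, not exactly.

## 4. Synthetic cohorts

The generator produces the trial-level 60 Hz yaw traces the analysis
consumes:

```
yaw(t) = drift + g_m · scale_session · f(speed, contrast, radius) · sign(dir) · h(t) + ε(t)
```

* **Tuning surface `f`** (ground truth, deg/s): concave quadratic in
  speed, zero at speed 0, maximum `peak_olr` at `peak_speed` (defaults
  35.0 deg/s at 57.2 deg/s), times saturating Michaelis–Menten-style
  factors in contrast (half-saturation 0.30) and dot radius
  (half-saturation 0.80°), each normalized to 1 at the reference levels
  (contrast 0.68, radius 1.4°).  Because `f` is exactly quadratic in
  speed, the pipeline's weighted quadratic fit is unbiased for the peak —
  by design, so that recovery studies test the pipeline, not the
  mismatch between generator and model.  One consequence: the gain curve
  `f(s)/s` of this generator is linear and decreasing, so the synthetic
  gain optimum sits at the lowest tested speed (reported as a flagged
  boundary peak).  Real cohorts show interior gain optima; the stand-in
  tuning shape does not emulate that.
* **Gain spread `g_m`**: per-mouse multipliers log-spaced with max/min
  ratio `gain_spread` (default 3, emulating the near-threefold amplitude
  spread between weakest and strongest responders), rescaled to
  arithmetic mean 1 so the cohort mean equals `f`.
* **Dynamics `h(t)`**: first-order (exponential) step response with
  latency 0.10 s and time constant 0.12 s (small per-mouse jitter, SD
  0.02 s).  These are stand-ins — the assay literature does not
  characterize single-trial dynamics — chosen as plausible reflexive
  locomotor values whose response sits at >99.9% of plateau throughout
  the 1–2 s measurement window, which is the premise of that window
  choice.  The decay after motion offset uses the same time constant.
* **Noise**: white Gaussian at the sample level (default SD 15 deg/s)
  plus a per-trial constant baseline offset (default SD 3 deg/s)
  standing in for slow forward-running bias.  This is the simplest model
  that makes both the 100 ms smoothing and the 500 ms baseline
  subtraction consequential.  Not emulated: autocorrelated locomotor
  noise, bouts/pauses in running, session-level drift within a session,
  eye movements, and any closed-loop visual feedback (the rig is
  open-loop by head fixation).  Passing recovery tests therefore
  demonstrate correctness of the analysis chain under this noise model,
  not robustness to every feature of real treadmill data.
* `session_scale` can multiply response amplitude per session (used to
  emulate a reflex that strengthens over the testing period in the
  consistency studies).  Everything is deterministic under a seed.

## 5. Preprocessing

Order of operations: smooth, then baseline, then window average — the
smoothing-first order slightly affects baselines and is fixed here.

* **Boxcar**: 100 ms = exactly 6 samples at 60 Hz, centered with a
  3-left/2-right split (the phase is not documented; centering minimizes
  latency bias in the OLR window); windows shrink symmetrically at trace
  edges so constants pass unchanged.
* **Baseline**: mean of the final 30 samples (500 ms) before motion
  onset, subtracted as a scalar.
* **OLR scalar**: mean over the half-open window [t₀+1 s, t₀+2 s) — 60
  samples, half-open to avoid double-counting the boundary sample.
* **Zero-speed correction and folding**: per mouse,
  `((R−Z) + (−1)(L−Z))/2` on condition means (traces or scalars).  All
  zero-speed trials (both direction labels) pool into the zero curve
  `Z`, so the folded zero-speed response is identically 0 — a useful
  invariant, checked end-to-end.  The two onset times are pooled as
  repeats.
* **Normalization**: each mouse's folded tuning vector (nonzero speeds
  only; the zero entries are identically 0) is z-scored and rescaled by
  the *population mean and SD*, taken as the across-mouse averages of
  the per-mouse curve means and SDs (ddof = 0).  After the operation all
  mice contribute equally to condition means, and for balanced tables
  the pooled mean — hence curve amplitude in physical deg/s — is exactly
  preserved.  The alternative convention of rescaling by the pooled SD
  over all mouse × condition values would stretch every curve by the
  between-mouse variance ratio (≈1.6× at a threefold gain spread) and
  systematically inflate peak-height estimates; `olrkit` deliberately
  uses the amplitude-preserving convention.  Mice with zero variance
  across conditions are rejected as degenerate.
* **Summaries**: the mouse is the unit of replication — condition means
  and SEMs are computed over the per-mouse normalized OLRs; each
  condition gets a two-sided one-sample t-test against 0 (α = 0.05,
  flagging the open/closed plotting convention); gain = OLR/speed is
  defined for speed > 0 only.

## 6. Fitting and inference

* **Weighted least squares**: condition means fitted with residuals
  weighted linearly by inverse SEs, i.e. minimize `Σ((y−ŷ)/SE)²`
  (implemented via WLS with weights `1/SE²`).  Reported R² is weighted,
  `1 − RSS_w/TSS_w`, with TSS about the weighted mean.  Curve fits use
  the 8 (or 4) nonzero-speed condition means, matching the degrees of
  freedom a reader would reconstruct from the F statistics.
* **Surfaces**: `polyMN` terms `x1^i x2^j`, `i ≤ M`, `j ≤ N`,
  `i+j ≤ max(M,N)` — the rule that reproduces the 6/9/9/10 parameter
  counts of poly22/poly23/poly32/poly33.
* **Model selection**: stepwise-up nested F-tests on weighted RSS
  (`F = ((RSS_s−RSS_l)/Δp)/(RSS_l/(n−p_l))`, p-values from the F
  distribution), accepting the larger model at p < 0.05, stopping at the
  first rejection.  For surfaces the ladder is poly22 → {poly23 or
  poly32, whichever improves more} → poly33.  Whether weighted or
  unweighted RSS enters the original F statistics is not documented;
  weighted RSS is used consistently here.  Empirical type-I error of the
  test is verified to sit in [0.03, 0.07] over 2000 null simulations.
* **Peaks**: 1-D peaks from the analytic critical points of the fitted
  polynomial plus interval endpoints; surface peaks from a 121×121 grid
  seed refined by bounded L-BFGS (keeping the better of seed and
  refinement).  Maxima on the domain boundary are flagged; a quadratic
  with no interior maximum is additionally flagged degenerate.  The
  finder agrees with dense grid search on random surfaces to grid
  resolution.
* **Bootstrap peaks**: 200 resamples (with replacement) of the
  mouse × condition points; each resample recomputes condition means and
  SEMs and refits.  Resamples in which any condition ends with fewer
  than two points or zero SEM cannot be refit with finite weights and
  are redrawn (counted and logged); in the all-zero-SEM case (noise-free
  data) the refit falls back to equal weights.  Peak uncertainty is
  reported as the bootstrap SD (the conventional headline number), the
  2.5/97.5 percentile interval per axis, and for surfaces a 95%
  normal-theory ellipse from the bootstrap peak covariance (the original
  ellipse construction is not documented; percentile CIs are pointwise).
* **Consistency splits**: `within_session_half` partitions each
  session's trial sequence at its midpoint; `early_vs_late_sessions`
  splits each mouse's sessions at the middle session index (late half
  includes the middle).  Each partition runs the full pipeline; the
  report contains both results objects, the per-axis overlap of the two
  95% peak-location intervals, and the amplitude ratio of the two mean
  curves.

## 7. Validation studies and problem sizes

`olrkit.studies` packages the simulations used for validation: F-test
calibration (2000 null curves at 8 speeds), model-order selection rate
(500 curves from a quadratic truth at moderate noise), a 50-replicate
end-to-end recovery study at the full study scale (6 mice × 36 conditions
× 70 repeats, ~15k trials per replicate, 200-sample bootstrap), and the
two split studies.  These sizes make the whole validation suite run in
well under a minute while keeping Monte-Carlo error small relative to the
margins being tested (e.g. binomial SE ≈ 0.5 percentage points on the
type-I error at n = 2000).  At these sizes the recovery study covers the
true peak speed and height in ≈92–96% of replicates.

## 8. Known limitations

* The generator's tuning is exactly quadratic in speed; it cannot probe
  model-misspecification bias in the quadratic fit, only the chain's
  correctness under a correct model.
* Percentile bootstrap intervals on 48 points can undercover slightly
  (a percent or two below nominal); the recovery criterion (≥90%
  coverage) has margin for this.
* The LUT inverts cell-by-cell and asserts cell-local invertibility; a
  calibration with folded (non-invertible) cells is rejected rather than
  repaired.
* Physical rendering (OpenGL primitives, gamma, anti-aliasing), eye
  tracking, forward-speed analysis and session wall-clock bookkeeping
  are out of scope.
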