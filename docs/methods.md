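# Methods

This note documents the model equations, parameter conventions, the scope
of the synthetic generator, numerical choices, and known limitations.
Everything stated here is either a definition or a property computed by the
package's own tests and acceptance script.

## Coordinate conventions

All orientations are Fick-style yaw/pitch angle pairs in degrees.

* World frame: right-handed, +x right, +y up, +z forward (meters).
* Yaw rotates about +y (positive = rightward), pitch about the rotated x
  axis (positive = upward). The forward unit vector for angles (y, p) is
  `d = (cos p · sin y, sin p, cos p · cos y)`, i.e. `R_y(yaw) · R_x(−pitch)`
  applied to +z.
* `eye` traces are eye-in-head (`head_frame`); `head` and reconstructed
  `gaze` traces are in `world_frame`. `EffectorTrace` enforces the
  effector/frame pairing.

## Gaze reconstruction

`reconstruct_gaze(eye, head, mode)` supports two compositions:

* **compose** (default): the gaze direction is
  `R_head · d_eye`, with yaw/pitch re-extracted from the composed forward
  vector. This is exact for the direction of the line of sight.
* **additive**: `yaw_g = yaw_e + yaw_h`, `pitch_g = pitch_e + pitch_h`, the
  small-angle approximation common in practice.

The two agree to 0 when either effector is at rest. Over a ±15° grid in
all four angles the mean 3-D angular separation between the modes is
≈0.26°; the worst corner of that box reaches ≈1.6°. That worst-case gap is
a property of rotation geometry (Euler angles do not add), not of either
implementation, so agreement tolerances are stated as expectations over
the domain.

Validity flags propagate with AND; a sample is usable only when both the
eye and the head sample are valid.

## AOI labeling

Scene regions are planar rectangles (`PlanarRect`: origin plus two edge
vectors). A gaze sample is labeled by intersecting the forward ray from
the eye origin with each rectangle (`intersect_plane`, parametric
ray–plane solution; rays parallel to, behind, or missing the bounds return
no hit). The default `SceneGeometry` places a 2.8 m × 1.6 m central screen
2.2 m ahead and a 16.4 cm × 12.4 cm device 0.7 m away at yaw +20°, pitch
−15°. The device is tested before the screen so that a device glance is
never mislabeled as screen; invalid samples are labeled `other`.

## Eye–head coordination slopes

Within the visual-search trial windows (seven 6 s windows per scenario),
simultaneous (eye, head) angle pairs are collected per axis. Pairs falling
into sparsely occupied cells of a 1°×1° grid (fewer than 20 occurrences,
grid anchored at 0°) are discarded as artefacts; the filter is applied per
participant × condition, never to pooled data. The reported slope is the
OLS regression of head angle (response) on eye angle (predictor). The
acceptance script verifies that the filter biases a known generative slope
by at most a few thousandths.

## Time-based transition entropy

1. **Binning** — the full-scenario trace is cut into half-open 120 ms bins
   (≈ the minimum fixation duration; 3250 bins for a 390 s session at
   120 Hz). Each bin is reduced to the net displacement
   `sqrt(Δyaw² + Δpitch²)` between its first and last valid sample (a net
   distance, not an arc length). The trailing partial bin is dropped; bins
   with >50 % invalid samples are flagged invalid.
2. **States** — the default policy is shift/stay: a bin is a *shift* if
   its displacement exceeds θ = 1°, else a *stay*. Alternative policies:
   k-quantile displacement states and per-bin majority AOI labels (gaze
   only).
3. **Transition model** — consecutive valid-bin pairs are counted into a
   first-order transition matrix. Pairs spanning an invalid bin are
   dropped, so dropouts do not fabricate transitions. The stationary
   weights `p_i` are the row marginals of the empirical joint, which makes
   the model internally consistent by construction.
4. **Entropy** — the default (`mode="standard"`) is the Shannon
   conditional entropy of the next state given the current one:

   `H = − Σ_i p_i Σ_j p(j|i) · log2 p(j|i)`

   normalized by `log2(n_realized_states)` into [0, 1] (0 by convention
   for a single-state chain). `mode="literal"` instead places the *joint*
   probability inside the logarithm; it is provided for comparison with
   formulations that print the equation that way and is not the Shannon
   conditional entropy.

Closed-form anchors (verified in the tests): deterministic alternation
→ 0; i.i.d. uniform two-state → 1; the two-state chain with rows
(0.9, 0.1) and (0.5, 0.5) → 0.5575 bits via its stationary distribution
(5/6, 1/6), matched within 1e−3 by a 10⁶-step simulated chain, and the
standard mode agrees with a brute-force pair-enumeration oracle to 1e−12.

## Synthetic generator

`simulate_session` generates one 390 s scenario at 120 Hz:

* **Latent fixation sequence** — semi-Markov alternation between road,
  device and mirror targets. Outside trials the driver mostly watches the
  road with Poisson refixations and mirror glances whose rates scale with
  `state_randomness` (the generator's scanning-complexity dial). Inside
  each of the `n_trials = 7` trial windows the target alternates between
  device and road with exponential dwells scaled so that the switch rate
  equals `switch_rate_in_trial`.
* **Plant dynamics** — gaze and head angles follow first-order lags toward
  their piecewise-constant targets (`tau_gaze_s = 0.05`,
  `tau_head_s = 1.5`), implemented with `scipy.signal.lfilter` plus an
  exact transient correction. The head tracks `head gain × target` where
  the gain is per-axis (`head_gain_yaw`, `head_gain_pitch`); each device
  visit draws its own head-recruitment share (SD `head_recruit_sd`), so
  head involvement varies glance-to-glance.
* **Postural sway and VOR** — an Ornstein-Uhlenbeck sway
  (`tau_sway_s = 3`, SD `head_sway_sd × state_randomness`) is added to the
  head and subtracted from the eye, modeling vestibulo-ocular
  compensation: the head oscillates while gaze stays on target. This is
  the mechanism that produces *negative* head-on-eye slopes — during
  device glances the head parks near the device while corrective eye
  flicks return toward the road, anti-correlating the two angles. A pure
  first-order low-pass head cannot produce a negative slope (its
  eye–head covariance is `g(1−g)·var ≥ 0`).
* **Noise and jitter** — white measurement noise per effector
  (`noise_sd_eye`, `noise_sd_head`) and fixation-target jitter
  (`fixation_jitter_sd`).
* **Condition/group cells** — `default_params(condition, group)` applies
  the degraded-vision offsets: more head recruitment
  (`head_gain_yaw` 0.15 → 0.30/0.38), lower scanning randomness
  (`state_randomness` 0.55 → 0.50/0.45) and longer device dwells
  (1.5 s → 2.0/2.2 s), with the higher-degradation group shifted further.
  The entropy decrement is calibrated so the condition main effect on eye
  entropy lands near η² ≈ 0.25 on a 21-participant cohort.
* **Cohorts** — `simulate_cohort` draws per-participant trait offsets
  (SD 0.05 on `state_randomness` and `head_gain_yaw`) that are identical
  in both of a participant's conditions, inducing the within-subject
  correlation of a repeated-measures design. All randomness descends from
  one `numpy.random.SeedSequence`, so cohorts are reproducible and
  per-session streams are independent.

Generator scope: it reproduces the *structure* of dual-task scanning data
(state sequences, plant lags, sway, noise, design cells), not any specific
person's kinematics. Saccade main-sequence dynamics, blinks, torsion,
vergence and vehicle motion are intentionally out of scope.

## Statistics

* **KS test** — `scipy.stats.ks_2samp` (asymptotic p-values) comparing
  pooled rotation distributions between conditions.
* **Box-Cox** — applied to an outcome only when a Shapiro-Wilk pre-test
  rejects normality at α = 0.05; non-positive samples are shifted to
  positivity first; λ is the scipy maximum-likelihood estimate. The
  transform provenance (λ, shift, skew before/after) is recorded in the
  run manifest.
* **ANOVA** — two modes for the 2 (condition, within) × 2 (group,
  between) design:
  * `paper_df` (default): fixed-effects two-way ANOVA on the session
    values (type II sums of squares; for this balanced layout types
    I/II/III coincide). A 21-participant cohort gives df = (1, 38) for
    every effect — the degrees-of-freedom layout printed by analyses that
    treat the 42 sessions as independent. η² = SS_effect / SS_total.
  * `mixed`: conventional mixed ANOVA (pingouin), with the
    within-subject error term from participant × condition cells and
    partial η².
* **Tukey HSD** — Tukey-Kramer studentized-range comparisons across the
  four condition × group cells, computed directly from cell means and the
  pooled MSE with `scipy.stats.studentized_range`; the critical value is
  cached per (k, df, α). Cells with fewer than 2 observations are
  excluded and recorded.
* **Calibration** — under null simulations the KS test and each ANOVA
  effect reject within [0.035, 0.065] at α = 0.05, and the Tukey
  family-wise error rate stays below 0.07 (verified in the acceptance
  tests and re-measured by `scripts/acceptance.py`).

## Numerical choices

* CSV round-trips are bit-exact: files are written with Python's
  shortest-repr float formatting and read with pandas'
  `float_precision="round_trip"` parser.
* Binning and transition counting are fully vectorized
  (`np.unique`/`searchsorted`/`np.add.at`); a 42-session full-length
  cohort analyzes in ≈10 s on one CPU.
* `0 · log 0 = 0` throughout the entropy computations.
* Density-grid bins and time bins are half-open and anchored at 0 so
  results do not depend on data ranges.
* All seeds pass through `numpy.random.SeedSequence`; no global RNG state
  is used.

## Limitations

* The `paper_df` ANOVA treats repeated sessions as independent; it exists
  to reproduce a published degrees-of-freedom layout. For inference on
  real data prefer `mode="mixed"`.
* The shift/stay entropy depends on the θ = 1° threshold and the 120 ms
  bin width; values are comparable only across analyses using the same
  settings. The quantile policy removes the threshold dependence at the
  cost of adapting states to each session.
* The additive gaze-reconstruction mode degrades away from primary
  position (see the compose/additive comparison above); compose is the
  default.
* Normalized entropies are divided by log2 of the *realized* state count;
  sessions realizing fewer states than the policy allows are normalized
  over fewer states.
* The generator's measurement-noise and sway amplitudes are plausible but
  not fitted to any recorded dataset; absolute entropy or slope values
  from synthetic data should not be compared against real recordings,
  only against other synthetic runs.
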