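# Methods

This note records the models, conventions, and numerical choices behind
`tendrilkin`, and what the validation suite does and does not establish.

## Coordinate and unit conventions

Space is measured in millimetres, time in hours. `y` is the vertical growth
axis; all stimulus distances live on the horizontal XZ plane, so arbitrary
vertical growth never affects the distance profile. The trajectory dialect
(CSV; one row per plant and sample) makes both units explicit in its
documentation rather than guessing any particular camera calibration or
frame rate — tracking systems differ, and nothing downstream depends on the
absolute scale.

## Distance to the support

`s_i` is the XZ-plane Euclidean distance between the tendril tip and the
support **axis**, minus the support radius, floored at zero — i.e. distance
to the support *surface*, so that `s ≈ 0` means contact for any support
thickness. Measuring to the surface rather than the axis is a package
convention (either is defensible); it makes the grasp criterion independent
of support diameter. A biological support moves with its own circumnutation:
its per-timestamp axis displacement (`motion_trace`, aligned with the
trajectory's clock) enters the distance sample-by-sample. If support and
trajectory clocks differ, resample the trace to the trajectory clock first;
the package requires aligned lengths rather than interpolating silently.

No-support (CC) plants have no stimulus. Their profile — needed only for
duration and velocity-amplitude summaries — uses the XZ distance from the
plant's own starting tip position as reference. Submovement analysis is
refused for CC: there is no grasping phase, hence no homing window.

## Discrete profiles

Velocity, acceleration, and jerk are first-order divided differences, each
aligned to the right endpoint of its interval (v on t[1:], a on t[2:], j on
t[3:]). No smoothing is applied by default; a centred moving average of odd
window length is available and its use is recorded in the run log, because
zero-crossing counts are noise sensitive. Time-scale covariance holds
exactly: scaling t by c scales v, a, j by 1/c, 1/c², 1/c³.

## Terminal window and submovement counts

The window is defined on movement **time** by default: all samples with
`t_i ≥ t_0 + 0.9 (t_end − t_0)` (fraction configurable), with a relative
tolerance of 1e-9 so grid points landing exactly on the threshold are
included. A sample-count basis is available for irregular-sampling
robustness checks. Profiles are differentiated over the full movement first
and windowed afterwards; a derivative value is "inside" the window when the
right endpoint of its interval is. The two orders (window-then-difference)
agree away from the single edge value, which tests verify.

A zero-crossing is a sign change between consecutive values after snapping
`|x| ≤ deadband` to zero. A run of zeros counts as at most one crossing and
only when the flanking signs differ, which makes counts stable under
duplicated samples. The behavioural deadband defaults to 0 (raw crossings).
Independently of it, counts apply a **numerical zero floor** per profile:
divided differences of a distance series of scale `|s|` carry rounding error
of order `eps·|s|/dt` per derivative order, so derivative values below
`1e-10·max|s|/dt` (times `2/dt` per further order) have meaningless signs —
an exactly constant-speed approach would otherwise show spurious
acceleration crossings. The floor scales with the data, preserving
positive-scale invariance of the counts, and is many orders of magnitude
below any physically meaningful signal.

## Endpoint variability

Per plant, over the terminal-window 3D point cloud: RMS distance from the
window centroid (default), or the mean of those distances. Both are
invariant to rigid translation and rotation. For a stationary tip with
isotropic per-axis jitter SD σ the RMS estimator converges to σ√3. The
estimator over the terminal cloud is a package convention — the quantity is
often reported without a definition, and published values for it vary by
more than an order of magnitude between conditions, consistent with a
squared or cumulative measure; neither shipped estimator claims to match any
particular published scale, only the between-condition ordering.

## Group statistics

Descriptives use linear-interpolation percentiles (the default of common
statistics suites; IQR depends on this choice). Shapiro-Wilk, Kruskal-Wallis
(tie-corrected H against chi-square with k−1 df), and Tukey HSD delegate to
scipy; the Dunn rank-based post hoc with Bonferroni adjustment is
implemented directly (it is the conventional follow-up to a Kruskal-Wallis;
Tukey is offered because some published analyses use it in that position).
Identical values across all groups yield H = 0, p = 1 rather than an error.

The pooled two-sample t is implemented from summary statistics —

    sp² = [(n₁−1)s₁² + (n₂−1)s₂²]/(n₁+n₂−2),  t = (m₁−m₂)/(sp·√(1/n₁+1/n₂))

— with Cohen's d = (m₁−m₂)/sp, and the raw-sample path computes summaries
and delegates, so the two routes agree exactly. d's standard error uses the
large-sample approximation `SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))` with
a normal-quantile 95% CI; exact noncentral-t intervals are out of scope, and
the SE/CI are reported for orientation only.

The shipped reference summaries (`tendrilkin.reference`) carry per-condition
means and SDs for the submovement measures with n = 8 per group — the group
size implied by the reported df = 14. Re-deriving the four t statistics and
the d values from these summaries is the package's exact-replication check.
One caveat is inherent to summary-level re-analysis: summaries rounded to
three decimals propagate an uncertainty of about ±0.001 into t, so a
re-derived t can differ from an originally published one in the last printed
digit (the acceleration-count t is such a case: −2.1095 from the printed
summaries).

## The synthetic generator

No generative model of circumnutation is established for this setting; the
simulator is the simplest construction that realises every measured quantity
with controllable ground truth. Three phases:

1. **Exploration** — elliptical oscillation (radii ~25–35 mm, period
   ~1.1–1.6 h, order-of-magnitude choices for pea tendrils) around a centre
   rising at 2 mm/h.
2. **Approach** — the centre-to-surface gap decays exponentially, reaching
   the homing start distance (default presets: 60 mm for the artificial
   support, 20 mm for the biological one) after `approach_gain` = 4 e-folds
   by homing onset, while the oscillation amplitude tapers to 15%.
3. **Homing** — the last 10% of movement time. The distance-to-surface
   follows a deterministic schedule of k+1 alternating monotone runs
   (valley levels decaying linearly to zero, rebounds recovering 30% of the
   preceding drop), so the velocity profile reverses sign exactly k times:
   k is the injected velocity-submovement count, drawn per plant as a
   rounded normal. Within each run, step magnitudes grow geometrically
   (8% per sample, compound growth capped at ~e³ per run) so acceleration
   and jerk are genuinely nonzero with deterministic sign patterns;
   their crossing counts arise consequently and are recorded as ground
   truth by applying the pipeline's own counting rule to the noiseless
   series. Totals are therefore affine in k, which is what makes a
   configured standardized effect on totals recoverable.

Default geometry: a 600 mm tall, 12 mm diameter pole 120 mm from the plant;
the biological support is a 5 mm stem that sways with 4 mm amplitude.
Presets set the biological condition slower and longer (duration 111 ± 20 h
vs 81 ± 15 h, sampled at 0.03 h) with fewer injected submovements
(48 ± 13.1 vs 67.1 ± 20.5), echoing the magnitudes reported for this
paradigm. The no-support preset ends in a monotone drop below the starting
height with no grasp.

Presets default to **noise-free coordinates**. This is deliberate: discrete
acceleration and jerk amplify per-sample position noise by 1/dt² and 1/dt³,
so at 0.03 h sampling even 0.05 mm of tracking noise makes raw third-order
zero-crossing counts pure noise — published count magnitudes are only
consistent with low-noise tracks analysed raw. `observation_noise_sd` and
`terminal_jitter_sd` remain available for sensitivity analyses (the
velocity-count recovery check runs at signal-to-noise ratio 10).
Condition-dependent endpoint dispersion arises from the homing geometry (a
wider homing start spreads the terminal cloud) rather than injected jitter.

Determinism: every plant draws from its own `numpy.random.default_rng`
stream keyed on (seed, plant index, condition), so outputs are
bit-reproducible across runs and platforms and independent of how many
plants are simulated.

What the generator does **not** emulate: tissue mechanics, phototropic or
chemical signalling, amplitude/period distributions fitted to any real
cultivar, occlusions or tracking dropouts, and autocorrelated measurement
error. Passing the validation suite therefore shows the *pipeline* is
correct and calibrated on movements with this structure, not that real
tendril data meet the generator's assumptions.

## Validation scale and design choices

The acceptance checks use 100 plants for count recovery, 2000 simulated
studies of n = 8+8 for the t-test's type-I error (observed ≈ 0.05), 200
studies for effect-size recovery (a configured d* = 1.33 on totals is
recovered within ±0.25; small upward bias ≈ Hedges' small-sample factor),
and 50 plants per condition for the preset contrasts — sizes chosen to make
Monte-Carlo error small relative to each tolerance.

Open choices resolved as package conventions (all logged per run): terminal
window on a time basis; deadband 0; distance to the surface, not the axis;
mean velocity as mean |v| (circumnutation makes signed ds/dt average to ~0,
and reported group means for this measure are strictly positive); movement
end = grasp sample for grasping plants and last tracked sample (or an
explicit drop index) otherwise; for odd injected counts the final rebound is
capped at 8% of the last drop, so those movements end within a fraction of a
millimetre of the surface rather than exactly on it.

## Known limitations

* Raw zero-crossing counts on measured (noisy) accelerations and jerks are
  dominated by noise; use the deadband or smoothing options, and expect
  counts to depend on them.
* The Dunn-Bonferroni post hoc cannot reach p < 0.05 for adjacent groups at
  n = 8 per group even under maximal rank separation; this is a property of
  the test, not a bug.
* Cohen's d CI is a large-sample approximation, optimistic at n = 8 + 8.
* `simulate_study` returns per-plant support specs (biological supports get
  per-plant motion traces); file-based runs use one static support per
  condition.
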