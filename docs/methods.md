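# Methods

This note documents the statistical models, the synthetic-study generator,
the numerical choices, and the known limitations of `hragree`.

## Alignment

Device HR series report sparsely and irregularly (integer gaps of 1–7 s by
default); the reference chest strap reports at 1 Hz. Matching is
*reference-driven*: reference points are the unit that is either matched or
excluded. Each reference sample is greedily matched, in time order, to the
nearest not-yet-used device sample within a tolerance (default 0.5 s — half
the 1 Hz reference interval, which makes matching unambiguous on integer
grids); exact distance ties break toward the earlier device sample. An
`earlier` tie rule (first unused sample within tolerance) is available. No
interpolation, smoothing, or outlier handling is applied, so error metrics
reflect the device's raw reports. The count identity
`matched + excluded = reference samples` holds per session and per segment
slice, and is logged in the run report.

Cross-correlation lag estimation and clock-drift correction are out of
scope: timestamps are trusted as reported.

## Error metrics and their summary

MAE = mean |device − reference| (bpm); MAPE = mean |device − reference| /
reference × 100 (%), with the reference as denominator since it is the gold
standard. Both are computed per device-session and stratum (whole session,
each climate chamber, each analyzed activity) and summarized across the
sessions of a device as median (IQR). Quantiles use linear interpolation
between order statistics (numpy's default, "type 7"); IQR values depend on
this choice, so it is fixed and documented. An empty pair set raises rather
than returning 0, because MAE = 0 is a meaningful (perfect) result.

Per-climate strata default to *all* tasks performed inside the chamber;
`climate_strata="activities_only"` restricts them to the three analyzed
activities instead.

## Repeated-measures CCC

Stacked reference and device observations are modelled as

    HR_ijk = mu + delta * device + a_i + e_ijk,
    a_i ~ N(0, s2_a),  e_ijk ~ N(0, s2_e),

a linear mixed model with one random intercept per participant and a fixed
method effect `delta` (device minus reference), estimated by REML
(statsmodels `MixedLM`). The concordance correlation coefficient is the
two-method variance-components form

    CCC = s2_a / (s2_a + s2_e + delta^2 / 2).

Design choices and degeneracies:

* This is the *minimal* random-intercept model: no subject × method
  interaction, no time or segment covariates, independent residuals. On
  time-structured data the shared within-subject HR dynamics (rest →
  exercise swings) therefore load on `s2_e` and count as disagreement,
  which deflates the CCC relative to formulations that model a shared
  time-varying signal. Simulations from the model itself recover the closed
  form exactly (e.g. s2_a = 100, s2_e = 25, delta = 0 → CCC = 0.8); on the
  synthetic protocol study the CCC ranks devices correctly but sits well
  below 1 even for an accurate device. Interpret it comparatively, not
  absolutely.
* Negative/boundary variance estimates are clipped to zero and logged. If
  the within-cell residual variance vanishes (noise-free input) the REML
  problem is degenerate and the balanced-ANOVA moment estimators are
  returned instead (logged).
* With a single subject the participant intercept is unidentifiable; the
  grouping unit falls back to the matched pair (time point), under which
  the model-based CCC coincides with Lin's concordance computed directly on
  the paired samples. Lin's single-measurement CCC is otherwise only an
  internal test oracle, not public API.
* statsmodels' default optimizer occasionally converges to a false
  zero-variance boundary (which also corrupts the fixed effects); fits that
  end on the boundary or fail to converge are retried with Powell's method
  and the solution with the higher REML log-likelihood is kept.

## Mixed-effects Bland–Altman

Device-minus-reference differences are modelled as
`d_ik = b + a_i + e_ik` with a participant random intercept (REML). Bias is
the fixed intercept `b`; the 95 % limits of agreement are
`b ± 1.96 * sqrt(s2_between + s2_within)`, using the normal quantile 1.96
(not a t quantile), matching conventional Bland–Altman practice. With one
observation per subject, or a single subject, the model reduces exactly to
the classic analysis (mean ± 1.96 SD of the differences, between-component
0, logged). Constant differences return collapsed limits equal to the bias.

## Comparison ladder

The unit of every between-device and between-condition test is the
per-session metric (one MAE or MAPE value per device session and stratum) —
the only exchangeable unit in a 10-sessions-per-device design.

* Shapiro–Wilk (alpha = .05) is computed per device × stratum × metric and
  logged in the run report; the ladder proceeds nonparametrically
  regardless, since session-level error metrics are generically skewed.
* Device factor: Kruskal–Wallis (tie-corrected H, chi-square reference)
  across the device groups at alpha = .05, uncorrected (one omnibus per
  metric). If it rejects, all 45 device pairs are compared by Wilcoxon
  rank-sum at alpha/45.
* Climate and activity factors: one Friedman test per device (complete
  blocks = sessions; incomplete blocks dropped and logged) at alpha/10 for
  a 10-device family. On rejection, the 3 condition pairs are compared by
  Wilcoxon signed-rank at alpha/3.
* Exact p-values are used for the pairwise tests when n ≤ 25 and the data
  are tie-free; otherwise the normal approximation with continuity and tie
  corrections. Zero differences are discarded (classic Wilcoxon; Pratt
  ranking available via `zero_method="pratt"`). Effect sizes are
  rank-biserial: r = 2·U1/(n1·n2) − 1 for rank-sum (U1 counting x > y pairs
  with ½ per tie) and r = (W+ − W−)/(W+ + W−) for signed-rank; r > 0 means
  the first sample tends larger.
* Bonferroni thresholds are compared unrounded and displayed at 4 decimals
  (.05/45 = .0011, .05/10 = .005, .05/3 = .0167).
* Friedman with two conditions is refused (it reduces to the signed-rank
  test); the chi-square reference makes the k = 3, n = 10 test conservative
  in the far tail — its exact attainable level at the .005 cut is 0.00198,
  computed by enumeration in the test suite.

## Synthetic study generator

The generator supplies data with the statistical structure the analysis
assumes; it emulates a chamber protocol, not any specific hardware, and its
defaults are fixed study conditions.

* **Protocol**: three climates — neutral (23 °C / 50 % RH), hot (36 °C /
  70 % RH), cold (10 °C / 40 % RH) — each with six fixed tasks: seated rest
  6 min, cognitive stressor (MIST) 4 min, seated recovery 2 min, steady
  walking 4 min, intermittent walking (30 s walk/stand bouts) 4 min,
  standing 2 min; 22 min per chamber. Chamber order is counterbalanced:
  even-indexed subjects run neutral–hot–cold, odd-indexed neutral–cold–hot.
* **Latent HR**: per subject, baseline ~ N(65, 7²) bpm (clipped to
  [40, 110]); segment targets add activity increments (rest 0, MIST +12,
  recovery +4, walking +45, standing +8; intermittent walking alternates
  the walking/standing targets every 30 s) and climate increments (hot +8,
  cold −3, neutral 0). HR relaxes toward the target with time constant
  tau = 40 s via `h[t] = h[t-1] + min(1, 1/tau)·(target − h[t-1])`, and a
  stationary AR(1) fluctuation (coefficient 0.9, innovation sd 2 bpm) is
  added to the relaxation path. Placing the innovation *inside* the
  relaxation recursion would amplify its variance by roughly tau², making
  the noise scale depend on tau; adding the AR process on top keeps the
  two parameters orthogonal while preserving the fixed-point behaviour
  (tau → 0 with zero noise pins HR at the target). The series is clamped to
  (0, 250] bpm with a logged warning. Activity and climate increments are
  plausibility choices producing light-to-moderate exercise HR ranges, not
  estimates of any real population; no published magnitudes exist for the
  climate effects in particular.
* **Device observation**: the truth is resampled on the device grid
  (regular, or integer gaps uniform on {1..7} s), then a per-subject
  calibration bias b_i ~ N(beta_d, sigma_b²) (drawn once per subject),
  i.i.d. noise N(0, sigma_e²), and artifact runs are added. Artifacts start
  per sample with an activity-dependent probability, last a geometric
  number of samples (mean 5), and either hold the last value or add a
  N(0, 25²) bpm excursion (mixed 50/50 by default) — mimicking PPG tracking
  loss under irregular motion. Device HR is floored at 1 bpm.
* **Design**: 45 subjects × one session each; nine wrist devices assigned
  round-robin two per subject (10 sessions per device) plus one finger ring
  worn by ten subjects — 100 device sessions, with wrist side alternating
  by subject parity. At most two wrist devices per subject are allowed
  (finger devices exempt). The ten default device models span a
  good-to-poor accuracy range (biases +0.5 to −12 bpm, noise 2.5–8 bpm,
  intermittent-walking artifact probabilities 0.05–0.30).
* **Seeding** is counter-based: every per-subject parameter, truth, and
  device stream is a `SeedSequence(master, spawn_key=...)` child, so adding
  subjects or devices never perturbs previously generated data, and equal
  seeds give byte-identical CSV output.

What the generator does *not* emulate: raw PPG/ECG waveforms, skin-tone or
demographic effects on optical signal quality, device firmware smoothing,
clock drift, thermoregulatory physiology, or HR variability structure
beyond AR(1). Passing tests therefore demonstrate the correctness and
calibration of the *analysis* under the stated error model, not the
accuracy of any physical device.

## Problem sizes and numerical conventions

The default study (45 subjects, 100 device sessions, ~396 k reference
samples) runs end to end in well under a minute on one CPU; unit tests use
reduced protocols (single-task or 6-minute chambers) and 8–20-replicate
Monte-Carlo checks, while the acceptance script uses 200–1000 simulated
subjects for variance-component recovery, 2000 null replicates for
type-I-error calibration, and 100 replicate studies for the
artifact-detection rate. Tolerances in the test suite come from closed
forms (e.g. LoA half-width 1.96·√(3²+4²) = 9.8) with allowances set from
binomial or sampling standard errors, and exhaustive enumeration oracles
(all C(8,4) labelings; all 2⁸ sign patterns) pin the exact Wilcoxon
p-values. Display tables round bpm/% values to 1 decimal and CCC to 2; the
machine-precision variants are written alongside.
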