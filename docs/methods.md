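# Methods note

This note documents the models implemented by `isoload`, the parameter
defaults and their units, what the synthetic session generator emulates (and
deliberately does not), the numerical choices made throughout, and the known
limitations. All quantitative statements here are either definitions or
properties verified by the test suite; the package makes no empirical claims
about human data.

## 1. Load model

### Prescription (`isoload.profiling`)

Relative intensity I (%MVC) for a target repetition maximum x:

    I(x) = 55.51 · e^(−0.0723 x) + 48.47

`reynolds_intensity` evaluates this; `reynolds_rm` inverts it on the open
domain (48.47, 103.98). MVC is the theoretical maximal voluntary torque at
zero angular velocity, extrapolated from a torque–velocity profile
(`fit_tv_profile`, linear `T(v) = T0(1 − v/v0)` or hyperbolic Hill form).
`prescribe_volume_equated` derives volume-equated sessions from a reference
volume load: repetitions per session = round(VL / I), with the per-set cap at
the floor of the theoretical RM.

### Load indexes (`isoload.load`)

With V = total repetitions, I = relative intensity (%MVC), R = total
inter-set rest (s), and α the RFD-decay rate constant (1/%MVC,
default −0.071):

| Index | Definition | Notes |
|---|---|---|
| VL | V · I | conventional volume load |
| dens_VL | VL / R | missing (`None`) when R = 0 |
| TL_RFD | V · I · e^(−αI) | fatigue-weighted load |
| TL_RFD_d | TL_RFD / R | missing when R = 0 |
| TL_RFD* | (Σ rep impulses) · e^(−αI) | impulse replaces count V |
| W_mech | Σ rep work / 1000 | kJ |
| sRPE | RPE · duration (min) | Borg 6–20 and CR10 variants |
| dens_RPE | RPE · V / R | missing when R = 0 |

At α = 0, TL_RFD reduces exactly to VL; at V = 0 it is 0; and the ratio of
TL_RFD at two intensities at equal volume is (I₂/I₁)·e^(−α(I₂−I₁)) in closed
form — these identities are asserted to 1e-12 in the tests.

### α calibration

`calibrate_alpha(slopes, intensities)` fits the per-repetition RFD-decay
slope as s(I) = b·e^(rate·I) (mono-exponential with the asymptote fixed at 0
by default, ≥3 intensity points required) and returns α = −rate with source
`"fitted"`. Degenerate inputs (constant slopes, too few points, failed fit)
fall back to the default −0.071 with source `"paper_default"`.
`calibrate_from_study` averages per-session slopes across participants at
each protocol intensity before fitting.

## 2. Synthetic session generator (`isoload.synth`)

The generator emulates a single-joint isokinetic leg-extension session with
analytic ground truth (`SessionTruth`) carried alongside every recording, so
each analysis stage can be verified end-to-end.

### What it emulates

- **Torque.** Each repetition is a half-raised-cosine ramp to the target peak
  torque (ramp time t_r = π·T_pk / (2·RFD_target)), a plateau for the rest of
  the prescribed range-of-motion duration, and a 50 ms release. Per-rep
  fatigue follows

      RFDpeak(n) = rfd_base·I/100 + s(I)·(n − 1),
      s(I) = fatigue_gain · e^(−fatigue_alpha · I),

  with fatigue_gain < 0, so the decline steepens exponentially with
  intensity. Exact truth values are closed forms: impulse
  = T_pk(dur − t_r/2 − t_down/2), work = v·impulse, and RFD0–100 truth is the
  secant from the 2.5 %-of-peak crossing t_on = (t_r/π)·arccos(0.95).
- **Velocity/position.** Constant prescribed angular velocity during
  contraction; position is its integral.
- **EMG (3 muscles, 2048 Hz).** White noise shaped in the frequency domain by
  a Gaussian band (SD 12.5 Hz) centred at the per-rep target MDF — by
  symmetry the band centre *is* the median frequency. MDF declines linearly
  per rep (base 85 Hz; slope 0.15 + 0.006·I Hz/rep) and RMS gain drifts
  +1 %/rep.
- **Heart rate.** Beat-by-beat R-R intervals from an underlying HR curve:
  mono-exponential on-kinetics toward hr_rest + Δ(I), decay during rests and
  recovery at the participant's hr_alpha toward an asymptote 3 bpm above
  rest. Beats are placed by a fixed-point sweep so each interval reflects the
  HR at the beat's end.
- **V̇O₂.** Linear rise during exercise (slope grows with intensity, capped),
  mono-exponential recovery; breath-stamped samples at a breath frequency
  that rises with V̇O₂. Truth includes the exact net-V̇O₂ integrals converted
  to energy at 21.3 J/mL.
- **NIRS.** ΔHbdiff (ΔO₂Hb − ΔHHb) declines linearly within each contraction
  at rate hbdiff_rate0 + hbdiff_rate_per_intensity·I and rebounds with a 5 s
  time constant; TSI mirrors it around a 70 % baseline.
- **Lactate.** Four point samples (baseline, onset, post-1, post-3) from
  Δ = 0.25·V − 0.03·I + 1.0/(1 + R/60) plus participant baseline.
- **RPE.** Borg 6–20 and CR10 from a weighted intensity/volume model with
  integer jitter.

### What it does not emulate

- No inter-muscle EMG cross-talk, motor-unit firing statistics, or
  non-stationarity within a contraction beyond the per-rep MDF/RMS steps.
- No torque overshoot/oscillation at the isokinetic speed transition, no
  gravity correction, no range-of-motion variability between reps.
- HR/V̇O₂ on-kinetics are first-order only (no slow component, no V̇O₂ drift);
  no cardiac variability structure beyond white R-R jitter.
- Lactate and RPE are point models, not dynamical systems.
- All channels are independent given the participant truth parameters; there
  is no shared beat-to-beat physiological noise.

### Parameters

Participant truth is drawn uniformly from `DEFAULT_RANGES` (sorted key
order, one `numpy` Generator per participant):

| Parameter | Range | Units |
|---|---|---|
| mvc | 200–320 | N·m |
| v0 (T–V zero-torque velocity) | 3.5–4.5 | rad/s |
| rfd_base | 900–1500 | N·m/s at 100 %MVC |
| fatigue_alpha | −0.071 (fixed) | 1/%MVC |
| fatigue_gain | −0.05 to −0.03 | N·m/s per rep |
| hr_rest | 55–75 | bpm |
| hr_alpha | −0.030 to −0.020 | 1/s |
| vo2_rest | 250–400 | mL/min |
| vo2_alpha | −0.022 to −0.015 | 1/s |
| lact_base | 0.8–1.5 | mmol/L |

Default protocols (`default_protocols()`): LI = 1×24 @ 58 %MVC, 1.68 rad/s,
no inter-set rest; MI = 2×9 @ 77 %, 0.92 rad/s, 180 s rests; HI = 5×3 @
93 %, 0.28 rad/s, 240 s rests. Mechanics are sampled at 148 Hz, EMG at
2048 Hz; range of motion 1.5 rad; 1 s inter-rep gap; 60 s baseline and 180 s
recovery. Noise defaults live in `NoiseConfig` (e.g. 2 % peak-torque SD, 3 %
RFD SD, 0.5 N·m sensor noise, 3 ms R-R jitter); `NoiseConfig.noiseless()`
zeroes all of them.

### Seeding

`np.random.SeedSequence(seed).spawn(...)` fans out one child per channel in
the fixed order ("mech", "emg", "hr", "vo2", "nirs", "lactate", "rpe"), so
generating a subset of channels never perturbs the others.
`simulate_study` spawns per-participant and per-session children the same
way and keeps every derived integer seed below 2³¹.

## 3. Signal core numerics (`isoload.signals`)

- **Low-pass filtering** is zero-phase (`sosfiltfilt`) Butterworth; because
  the filter is applied twice, the −3 dB design cutoff is a −6 dB point of
  the effective response.
- **Moving average** is centred; for even window lengths a symmetric
  trapezoid kernel of length w+1 (endpoints weighted 0.5) is used so the
  smoother introduces no half-sample phase shift; edges are normalized by
  the convolved kernel mass.
- **STFT PSD** uses Hann windows of 250 ms with 125 ms hop; the window count
  is exactly floor((N − win)/hop) + 1. Each row is one-sided and normalized
  so that its sum equals the energy of the Hann-weighted segment (Parseval
  convention), making MDF invariant to overall gain.
- **Median frequency** treats the spectrum as piecewise-uniform bins and
  linearly interpolates inside the crossing bin; a flat spectrum on [0, F]
  yields exactly F/2. A brute-force cumulative-search oracle cross-checks it
  on random spectra in the tests.
- **Mono-exponential fitting** (f(x) = b·e^(αx) + c) uses variable
  projection: a log-spaced rate grid with the linear pair (b, c) solved
  exactly at each candidate, followed by Levenberg–Marquardt polish.
  Options fix c = 0 and constrain the rate sign. Constant input returns
  b = 0, c = mean, `converged=False` rather than raising.
- **Segmentation** marks contraction where |velocity| exceeds 10 % of the
  protocol velocity, keeps episodes ≥ 0.2 s, and starts a new series
  (set) when the gap between repetitions exceeds 5 s.

## 4. Neuromechanics (`isoload.neuromech`)

- **Torque onset** is found by scanning backward from the repetition peak to
  the last sample at or below 2.5 % of the peak.
- **RFD0–100** is the secant over the first 100 ms after onset, with the
  onset refined to sub-sample precision by linearly interpolating the
  threshold crossing (the torque at onset is the threshold value itself).
  This removes the sample-phase jitter a grid-aligned onset would add.
- **RFDpeak** is the maximum of a Savitzky–Golay derivative (window 5,
  order 2) of the 10 Hz zero-phase-filtered torque; a windowed 100 ms
  mean-slope mode is available. The zero-phase filter slightly rounds sharp
  ramp corners, so RFDpeak on an ideal linear ramp is accurate to a few
  percent, not machine precision.
- Impulse and work are trapezoid integrals of torque and torque×velocity on
  the uniform grid (exact for constant and piecewise-linear signals).
- EMG per-rep features: rectification → 10 Hz zero-phase low-pass envelope →
  per-rep RMS normalized to rep 1 → 101-point time-normalized envelopes;
  MDF per rep from the Hann STFT above.
- **Fatigue slopes** are ordinary least squares of each metric against
  repetition number (≥ 3 reps required per series).

## 5. Systemic responses (`isoload.systemic`)

- HR is reconstructed from R-R intervals (60/RR at cumulative beat times →
  1 Hz interpolation → 10 s moving average).
- Recovery kinetics (HR and V̇O₂) are mono-exponential fits whose amplitude
  is rescaled to a stated reference time t_ref (exercise end), so the
  reported amplitude does not depend on where inside the recovery window the
  fit starts.
- Energy expenditure is 21.3 J/mL × the trapezoid integral of net V̇O₂, with
  the series interpolated at the exact window edges before integration.
- NIRS per-series ΔHbdiff rates take the best-r² linear fit over the first
  min(3, reps) repetitions of each series; lactate deltas are reported
  against the t_onset reference by default.

## 6. Reduction and hierarchical model (`isoload.reduction`)

- **Standardization** uses ddof = 1; constant columns are dropped and
  recorded; missing values are rejected (complete-case policy; mean
  imputation is opt-in and logged).
- **PCA** (scikit-learn) keeps all components with k recorded; the sign of
  each component is fixed so its largest-|loading| element is positive,
  making Dim.1 scores reproducible. `stacked_dim` regresses the response on
  the first k component scores (OLS) with a seeded bootstrap R² interval;
  `evaluate_tl_methods` emits a long-format table with one row per
  method × response plus Dim.1 and Stacked.Dim rows.
- **Hierarchical model** (random intercept, optional random slope):
  penalized marginal likelihood with β ~ N(0, (10·k_scale)²) ridge priors
  and half-Student-t(1, 0, 2.5) / (1, 0, 5) priors on the random-effect SDs
  (log-scale Jacobian included). β is profiled by penalized GLS; the
  log-SDs are optimized by Nelder–Mead; Wald intervals come from
  (ΣXᵀV⁻¹X + prior precision)⁻¹. The response is standardized internally
  and all estimates back-transformed, which makes the ICC invariant to
  affine rescaling of the response. A singular random slope (SD below
  1e-4 on the standardized scale) triggers an intercept-only refit and sets
  the `singular` flag. An optional random-walk Metropolis engine
  (`engine="mcmc"`, configurable chains/iterations/warmup) targets the same
  posterior and is cross-checked against the Laplace path in the tests.
- **Conventions:** ICC = σ²_b0 / (σ²_b0 + σ²_e). PVE values are variance
  shares of the intercept, slope, and residual components (a convention,
  flagged in the fit metadata, since no formula is standard). Conditional
  R² follows the fixed+random over total-variance definition. Bayes factors
  are not computed; random-structure comparisons are exposed as an
  information-criterion (AIC) difference.

## 7. Verification strategy and problem sizes

The acceptance-level tests use sizes chosen to balance statistical power
against a single-CPU budget: α recovery uses 20 replicates of 15
participants × 3 sessions at default noise (pass: within ±0.01 of the
programmed −0.071 in ≥ 90 % of replicates); hierarchical coverage uses 50
simulations of 30 groups × 20 observations (pass: ≥ 90 % Wald coverage of
the true fixed effects); the MDF oracle uses 500 random spectra. These sizes
are the package's own verification choices, not empirical claims.

## 8. Limitations

- The generator's analytic truth is exact for its own waveform family; real
  dynamometer data contain onset ambiguity, speed-transition artifacts and
  gravity effects the estimators here are not tuned for.
- `vo2_kinetics`' exercise slope is fit over the whole exercise window; on
  multi-set protocols the inter-set rests flatten it relative to the
  within-set slope programmed into the generator — it is a summary of the
  recorded window, not an estimate of the generator parameter.
- RFDpeak inherits a small bias from the prescribed zero-phase filter chain
  (see §4); RFD0–100 does not, thanks to the sub-sample onset refinement.
- The hierarchical model covers one grouping factor with at most one random
  slope; crossed or nested designs are out of scope.
- The Metropolis engine is a reference implementation (no adaptation beyond
  a fixed proposal scale); for large models the Laplace path is the
  recommended default.
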