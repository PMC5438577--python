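# Methods

## Model and procedure

crpkit measures the coordination of adjacent lower-limb segments with
the continuous relative phase (CRP). Each segment's state is reduced to
a point on its phase portrait — amplitude-normalised angular velocity
(normV) against amplitude-normalised angle (normθ), both in [−1, 1] —
and its phase angle φ is the portrait's polar angle. The CRP of a
couple is φ_proximal − φ_distal, evaluated pointwise on a normalised
0–100% movement base. The pipeline, per trial:

1. **Baseline correction.** The vertical ground-reaction force (GRF)
   is offset-corrected by subtracting the median of its lowest decile
   and clamping at zero; force plates drift, and the event threshold
   below assumes a zero baseline.
2. **Event detection.** Initial contact (IC) is the first sample of a
   maximal run with GRF ≥ 10 N; toe-off (TO) the first sample after it.
   Runs shorter than 25 ms are discarded (debounce), replacing the
   visual inspection a human operator would add to a pure threshold
   rule. Both constants are configurable (`grf_threshold_n`; the
   debounce is a module constant).
3. **Smoothing.** Segment angles pass a zero-lag (forward–backward)
   Butterworth low-pass, cutoff 6 Hz, order 4 per pass, no cutoff
   correction for the double pass — conventional gait-analysis
   practice. The dual pass squares the magnitude response, so the gain
   at 6 Hz is exactly 0.5; this is asserted in the tests.
4. **Differentiation.** Angular velocity is computed on the real time
   base (central differences, one-sided at the ends) *before* time
   normalisation, then interpolated — differentiating after
   interpolation would mix grid spacing into the units.
5. **Time normalisation.** Each analysis span is cubic-spline
   interpolated onto 101 equally spaced points (0–100%). For gait the
   span is one IC-to-IC cycle; every complete cycle in a recording is
   analysed and treated as one curve of the ensemble (a recording with
   k+1 ICs yields k curves) — discarding recorded cycles would only
   waste data. For the hop the span runs from movement onset (first
   sample where any segment's angular speed exceeds 5°/s, else the
   trial start) to the end of the recording.
6. **Phase windows.** Percent boundaries land on the grid by
   round-half-up, giving a deterministic partition of [0, 101):
   stance = [0, TO%), swing = [TO%, 101) for gait;
   preflight/flight/landing split at take-off and landing for the hop.
7. **Normalisation and phase.** Angle and velocity are min–max rescaled
   to [−1, 1] over the whole cycle (per-phase scope available via
   config; velocity can alternatively be divided by its peak magnitude,
   preserving the zero crossing). φ = atan2(normV, normθ) in degrees,
   unwrapped so successive differences lie in (−180°, 180°]. The
   two-argument arctangent is essential: a single-argument arctan is
   confined to two quadrants and cannot produce the continuous
   multi-revolution phase that unwrapping presupposes. A (0, 0)
   portrait sample has no phase; its value is carried forward and
   flagged (an error if it is the first sample).
8. **Summaries.** Per couple and phase window: RMS of the
   ensemble-mean CRP curve (default; mean of per-trial RMS via config)
   and the across-trials per-point SD averaged over the window
   (deviation phase; a within-curve SD is provided for single-trial
   use). SD across trials is the default because the study design —
   several trials per condition — only matters under that convention.
9. **Comparison.** Per parameter, subjects' condition means are
   compared with a paired test gated by Shapiro–Wilk on the paired
   differences (the quantity whose normality the paired t-test
   assumes): t if SW p ≥ α, else Wilcoxon signed-rank (zeros dropped,
   exact null at small n without ties, normal approximation otherwise),
   two-sided, α = 0.05, no multiplicity adjustment by default (Holm
   optional).

## Synthetic data

The generator emulates the study conditions rather than musculoskeletal
realism. Gait segment angles are sinusoids
θ_seg(t) = offset + A·sin(2πt/T + b_seg + η_cycle,seg) + ε(t) at
fs = 120 Hz: offsets/amplitudes chosen so the curves span segment-angle
ranges typical of level walking (thigh ≈ +28…−15°, shank ≈ +18…−59°,
foot ≈ +82…+1°); cycle T = 1.081 s with stride 1.47 m, i.e. 136 cm/s
and cadence ≈ 111 steps/min; stance fraction 0.62. The base phases
realise the couple lags so that the CRP ground truth is analytic: for
pure sinusoids φ = 90° − (ωt + b), hence CRP = b_distal − b_proximal =
the imposed lag, exactly, up to discretisation. Defaults: thigh→shank
lag 40°, shank→foot 60°.

η is a per-cycle, per-segment constant phase perturbation
(`jitter_sd`, default 5°), independent across segments, which maps
directly onto across-trials CRP SD (≈ √2·σ per point); ε is white
measurement noise (0.5° SD), mostly removed by the 6 Hz filter. The GRF
is a half-sine bump of 800 N spanning exactly the stance fraction of
each cycle — steep enough at its edges that the 10 N threshold detects
contact within a frame. Sacrum and heel markers advance at the
cycle-average speed, so stride and velocity are exactly recoverable.
The hop is one continuous sinusoidal arc over
preflight (0.5 s) + flight (0.25 s) + landing (0.5 s) with GRF bumps in
the contact phases and identically zero GRF in flight.

Cohorts draw subject-level couple lags (SD 5° between subjects), stride
(SD 10 cm) and walking speed (SD 7 cm/s) around the defaults, generate
5 gait + 3 hop trials per condition per subject (11 subjects by
default), and apply additive `effect` shifts to named model parameters
in the sleeve condition only — a known injected effect for recovery and
power checks. All outputs are pure functions of (model, seed, subject,
condition, trial index).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: multi-harmonic angle waveforms and
double-bump GRF profiles, within-cycle (continuous) timing warps,
soft-tissue artefact, asymmetry between limbs, and deviation-phase
magnitudes of real walking (the 20–50° across-trials SD reported for
human subjects
would correspond to σ ≈ 15–35°; the default 5° emulates timing jitter
only, keeping effect-recovery checks sharp). A `harmonics` option adds
higher-frequency content for realism tests without ground-truth claims.

## Numerical choices

- 101-point base; boundaries by round-half-up; windows must span ≥ 2
  grid points.
- Spline interpolation preserves span endpoints exactly.
- Amplitude normalisation refuses constant signals (tolerance
  1e−12·max(1, |max|)); phase continuity is guaranteed by construction
  of the unwrap (differences forced into (−180°, 180°], first sample
  unchanged).
- Zero-phase filtering requires ≥ 3·order samples; its reflection
  padding leaves a short edge transient, so response properties are
  measured on interior samples.
- All-zero paired differences short-circuit to a flagged degenerate
  comparison (p = 1) before Shapiro–Wilk, which is undefined for
  constant input.
- Results tables print means/SDs at 1 decimal and p at 3 decimals with
  p < 0.0005 rendered `<0.001`; trial CSVs are written at full float
  precision so write→read is the identity.

## Problem sizes

The test suite and `scripts/acceptance.py` use deliberately small
simulations — 2–3 cycles per trial, 20 seeds per jitter level, 2000
paired-null replicates at n = 11, one 11-subject cohort — chosen so the
whole battery completes in seconds while keeping Monte-Carlo error well
inside the asserted bands (e.g. the type-I band [0.03, 0.07] is ±4
binomial SEs wide at 2000 replicates).

## Known limitations

- Segment angles from markers use a two-marker sagittal projection per
  segment; no full lower-limb marker model, no joint angles, no
  frontal/transverse planes.
- One instrumented limb: the contralateral initial contact is
  approximated at mid-cycle for step width.
- Hop "movement onset" is a heuristic (angular-speed threshold); real
  preflight onset is not observable from the GRF alone.
- No statistical-parametric-mapping or mixed-effects curve analysis;
  comparisons are per scalar parameter.
- CSV is the only on-disk trial format.
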