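# Methods

This note documents the generative models, analysis conventions, numerical
choices and known limitations of `chronoluc`. Times are decimal hours from
the start of the recording throughout; "DD" is constant darkness, "LD" a
light/dark cycle, and an advance is a positive phase shift.

## Generative model

### Light input

A strain couples to light through two wavelength-selective pathways. Each
pathway has a relative action spectrum `A(λ) ∈ [0, 1]` on a fixed
monochromatic grid (default 360, 410, 460, 510, 660, 710, 760 nm) and a
coupling coefficient. The effective irradiance at wavelength λ and photon
flux `I` is

    E = c_csl · A_csl(λ) · I  +  c_blue · A_blue(λ) · I.

White light couples through both pathways at the mean of each spectrum's
values — white light appears only in entrainment phases, where spectral
fidelity is irrelevant. The all-zero spectrum is allowed and models a
pathway knockout. The default spectra give a red/violet-dominated first
pathway (peak 660 nm, secondary peak 410 nm, nothing in the far red) and a
blue-peaked second pathway; they are shape choices of this package, not
measurements.

### Light-degradable reporter (ROC15-like)

Between regime events the reporter obeys the linear ODE

    dR/dt = σ_dark · g(t) − (δ_dark + δ_L(t)) · R,

with `g = 1` in darkness and `g_light ∈ [0, 1]` under light (transcript
downregulation by light), and a saturating light-induced degradation rate

    δ_L = δ_max · h · E / (K_half + E).

`h` is a history factor modeling acute responses that appear only after
prior light exposure: `h = (1 − history_factor) + history_factor ·
min(1, L / L_sat)` with `L` the cumulative light-hours accrued before the
current segment and `L_sat = 12 h`. `history_factor = 0` makes the response
unconditional. `h` is frozen at each segment start, so every segment is a
constant-coefficient ODE. A variant archetype re-activates full synthesis
after a fixed number of hours of continuous light (`reactivation_after_h`),
splitting that light segment into two constant-coefficient pieces.

The default initial condition is the light-adapted steady state under the
regime's first light segment (cultures come out of growth light), falling
back to the dark fixed point for all-dark regimes.

Counts are `gain · R + background`, multiplied by unit-mean lognormal noise
of coefficient of variation `noise_cv`. Background defaults to 0; when it is
nonzero it enters before the noise, like a real dark-count offset, and is
deliberately *not* subtracted anywhere in the analysis chain. Delayed
chlorophyll luminescence is not modeled: the monitoring protocols this
package targets suppress it instrumentally by holding plates in darkness for
a few minutes before each reading.

### Circadian reporter and phase resetting

The clock is a phase-only oscillator, `dφ/dt = 2π/τ`, read out as

    counts = gain · B₀ · (1 + amp · e^(−d·t_DD) · cos φ) · e^(−r_drift·t) + background,

with amplitude damping `d` counted from the final release into DD and a slow
multiplicative drift included so detrending has something to remove. At
every dark→light transition the phase takes a discrete step

    Δφ = reset_gain · sin(φ − φ_ref) · D,

where `D` is the fraction of the ROC15-like reporter degraded within 30 min
of lights-on (computed from the reporter kinetics above, so pulses shorter
than 30 min act through the minimum the reporter reaches inside the
window). This ties clock resetting to reporter degradation, the working
model of the biology: a knockout that cannot degrade the reporter under red
light also cannot reset under red light.

The PRC is a single harmonic with its stable zero at φ = 0 and maximum
advance at φ = 3π/2. By default a simulation is initialized so the first
dark→light transition lands on the stable zero — the entrained-dawn
convention — which makes an unshifted entraining cycle kick-free and makes
two 5 h-advanced cycles re-entrain the default wild type by ≈ 5 h.

**Known limitation.** With a one-harmonic PRC the stable entrained dawn and
the time of maximal advance are rigidly 18 h apart. Measured PRCs for this
system put the maximal advance later (≈ 22 h after dawn, i.e. hour 34 of DD
after a 12:12 entrainment); reproducing both facts needs an asymmetric PRC
with a dead zone, which is out of scope. We keep the entrained-dawn
convention because quantitative re-entrainment behavior is what the
downstream analyses consume; in the canonical pulse protocol the simulator's
maximal advance falls at DD hour 30 rather than 34, and a 5-min saturating
red pulse there advances the default wild type by ≈ +1.5 h (observed values
in the motivating system: 1.6–1.9 h).

### Presets

All preset numbers are invented calibration choices — chosen once so the
archetypes reproduce the qualitative phenomenology, then frozen — not
measured values. Defaults (per hour unless noted): σ_dark = 100 counts/h,
δ_dark = 0.15 (dark fixed point ≈ 667 counts), δ_max = 25, K_half = 1.0,
g_light = 0.2, c_csl = 1.0, c_blue = 0.5, reset_gain = 1.2, τ = 24 h,
amp = 0.5, damping 0.003/h. The knockout preset zeroes `c_csl` and raises
`c_blue` to 1.2× the wild type (a mild blue sensitization; its true
magnitude is unquantified, so 1.2 is a placeholder). The degradation-null
preset sets δ_max = 0. Screen archetypes: Type 1 keeps synthesis on under
light (g_light = 1) with weak degradation (δ_max = 2); Type 2 re-activates
synthesis after 6 h of light; Type 3 sets history_factor = 1 (no response in
cycle 1, full response in cycle 2). Per-well random streams derive from
(seed, well id), so results are invariant to well insertion order.

## Numerical integration

Fixed-step RK4 with a 0.01 h internal step, with steps aligned to every
regime boundary (and to synthesis-reactivation switches), sampled onto the
output grid by linear interpolation of the dense node sequence. Because
every segment has constant coefficients, the RK4 update is the exact affine
recurrence `R_{n+1} = fp + (R_n − fp) · P₄(−bΔ)` (`P₄` the degree-4 Taylor
polynomial of the exponential); the implementation evaluates that closed
form vectorized, which is bit-identical to the step-by-step loop. With the
0.01 h step, `P₄` stays positive for decay rates up to ≈ 280/h, far above
any preset; a clamp guards pathological inputs.

## Analysis conventions

- **Detrending** divides each point by the centered moving average over all
  samples within ±12 h, inclusive at both ends. A centered (not trailing)
  window is used because it induces no phase lag. Points whose window is
  truncated by the record edge are computed from the available asymmetric
  window and masked as edge-affected rather than dropped. Wells with missing
  values are skipped and reported — silent interpolation would bias the
  minimum statistics downstream. Counts must be strictly positive and the
  grid must resolve the window (spacing ≤ window/4).
- **Reference normalization** takes "just before the pulse" as the last grid
  sample at or before the pulse start — no interpolation. Groups of one
  well report SD 0 with a singleton flag (screens have singleton wells);
  replicate SDs use the n−1 denominator.
- **Peak picking** smooths with a 3 h centered moving average, takes strict
  local maxima at least 16 h apart, and refines each peak time with a
  least-squares parabola over a ±3 h window around the grid peak. The wide
  fit matters: a three-point parabola passes sampling noise straight into
  the peak time (with 5% noise at 0.5 h sampling, only ~3/4 of periods land
  within ±0.3 h of truth), while the ±3 h fit recovers the period within
  ±0.3 h in ≈100% of runs. Peaks within 3 h of either record edge are
  discarded — their smoothing/fit windows are truncated and their times
  biased early. Ties resolve to the earliest time.
- **Period** is the mean spacing of successive peaks; **phase** is the time
  of the first used peak modulo the period. The reported phase is a
  peak-time phase; no cosinor or periodogram methods are used.
- **Phase shifts** compare peak times at one index (default: the latest
  peak all wells share, past post-stimulus transients), as control mean
  minus treated time, unwrapped into (−period/2, period/2]; the shifts of
  interest (≤ ~5 h on a 24 h period) are unambiguous under this rule. The
  p-value is a pooled-variance two-sample comparison of the treated
  per-replicate shifts against the control wells' internal deviations.
  Rhythm analysis starts 12 h into the record by default to skip
  entrainment transients.
- **Acute sensitivity** is 100 minus the post-pulse minimum (trace
  referenced to 100 just before the pulse), clamped below at 0, over a
  configurable search window (default 2 h — published traces reach their
  minima well inside that span; whether the original statistic used a
  global minimum or a fixed timepoint is unknowable, and the window
  parameter covers both readings). The complementation-assay level uses a
  6 h window by default and is not clamped. Irradiance-correction factors
  (e.g. plate lids attenuating 360 nm light) are metadata conventions, off
  by default.
- **Difference spectra** clamp negatives to 0, combine SDs in
  independent-error quadrature (a documented choice; the source analyses
  show no error bars on subtraction spectra) and take the pairwise minimum
  n.
- **Screen features** are read off a lightly smoothed trace (0.5 h centered
  moving average): the pre-dawn reference is otherwise a single sample, and
  its full measurement noise would propagate into every ratio. Acute drops
  use a 1 h window per cycle (a 2 h window would fold the slow Type 1
  decline into the "acute" drop). "Mid-to-late day" is the second half of
  each light phase. The classifier cascade is Type 3 → Type 1 → Type 2 →
  WT-like: absence of the acute response is the most specific phenotype.
  Default thresholds (cycle-1 drop < 20 → Type 3; < 60 → Type 1; midday
  rebound ratio > 2 → Type 2; cycle-2 drop exceeding cycle 1 by > 15 sets
  the conditional flag) were calibrated once against the simulator
  archetypes and are echoed verbatim in every call record. The operational
  criterion of the original screen was never published; these features and
  thresholds are an explicit substitute.
- **Statistics**: the t-test is classical pooled-variance Student (Welch
  behind a flag), two-sided by default, with `t = 0, p = 1` for degenerate
  zero-variance equal-mean input. No multiple-testing correction is applied
  — comparisons are reported per-test, mirroring the analyses this package
  reproduces. qPCR folds are target/reference ratios divided by the mean
  ratio of a baseline group, whose mean fold is therefore exactly 1; the
  standard-curve step that produces the relative quantities is upstream and
  out of scope.

## What the synthetic benchmarks do and do not show

The generator reproduces the statistical and mechanistic structure the
analyses assume: dark accumulation and acute light-triggered decline of a
reporter, wavelength-dependent sensitivity through two pathways, damped
free-running rhythms with slow drift, lognormal plate noise, and
degradation-coupled phase resetting. Benchmarks on it demonstrate that the
pipeline recovers known ground truth under realistic noise — they do not
demonstrate that real traces satisfy the model. In particular: real plate
noise has correlated components (position effects, luciferin depletion)
absent here; real PRCs are asymmetric with dead zones; real screens contain
phenotypes outside the three archetypes; and the absolute preset rates are
arbitrary calibration points, so only relative/normalized quantities should
be compared across presets. Benchmark problem sizes (100 seeds for period
recovery, 10 plates × 5+5 wells per re-entrainment condition, 7 wavelengths
× 5 wells per spectrum, 200 screen wells) keep the full suite within
seconds while leaving comfortable statistical margins.
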