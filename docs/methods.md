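# Methods

`qcmdlysis` implements a single-parameter procedure for deciding, from a
multi-overtone QCM-D measurement, whether a phage added to a bacterial
film on the sensor is lytic for that host. This note records the model,
its assumptions, the parameter defaults and their calibration, and the
numerical choices, in the package's own terms.

## Measurement model

A 5 MHz AT-cut quartz sensor reports, for each odd overtone
n ∈ {3, 5, 7, 9, 11}, the frequency shift Δf_n (Hz, stored raw, not
divided by n) and the dissipation shift ΔD_n (stored in the conventional
10⁻⁶ units). The acoustic shear wave decays into the liquid over the
penetration depth

δ_n = sqrt(η / (π·n·f₀·ρ)),

about 137.6 nm for n = 3 and 71.9 nm for n = 11 in water at 25 °C
(η = 8.9·10⁻⁴ Pa·s, ρ = 997 kg/m³ — the package's reference liquid; at
37 °C the depths are ≈121/63 nm). Because δ_n shrinks with n, low
overtones sense more of a thick, soft bacterial film than high ones, so
the *overtone spread* of the dissipation,

δD(t) = ΔD₃(t) − ΔD₁₁(t),

grows with effective film thickness and softness and collapses when
lysis reduces the film to a thin, stiff debris layer. That collapse is
the detection signal.

## Detection procedure

1. **Spread.** δD(t) = ΔD₃ − ΔD₁₁, pointwise on the shared grid.
2. **Normalization.** δD is divided by its maximum before the start of
   the second (phage) injection. This cancels the multiplicative
   sensor-sensitivity factor, which dominates sensor-to-sensor
   variability; a non-positive pre-injection maximum is reported as a
   degenerate baseline (no film formed) rather than silently normalized.
3. **Derivative classification.** Over the window from the end of the
   final flush to the end of the run, the normalized curve is smoothed
   with a centered moving average (halfwidth 10 samples = 5 min at the
   default 0.5-min grid) and differentiated with central second
   differences; the window endpoints use one-sided second differences
   with a stencil stride equal to the smoothing halfwidth. The call is
   *lytic* iff the mean (default rule; the sum is also reported) of the
   derivative curve is strictly positive; an exactly zero statistic ties
   to *non-lytic*. Rationale: a collapsing/recovering film is convex over
   this window (decaying collapse tail, accelerating survivor regrowth),
   while an uninfected film grows and saturates, which is concave.
4. **Drop fraction.** 1 − min δD / δD(injection start), the minimum taken
   over samples after the injection start up to 10 min past the final
   flush (the settling buffer). Negative values indicate growth.
5. **Fixed-timepoint readout.** Normalized δD at 240 min (linear
   interpolation), after the injection-induced drop has settled.
6. **Group comparison.** Welch's two-sample, two-tailed t-test on the
   readouts of the −phage vs +phage arms (unequal variances assumed;
   sensor variance differs between arms), with the usual star mapping
   (* p<0.05, ** p<0.01, *** p<0.001).

### Numerical choices

* Time windows are half-open [start, end) minutes; a sample exactly at
  the end of a window is excluded.
* Smoothing is applied to the **full** normalized series before the
  classification window is cut. The mean of a second-difference curve
  telescopes to the difference of the boundary slopes, so edge-padded
  smoothing inside the window would bias exactly the quantity the
  decision rests on; smoothing first lets real samples on both sides of
  the window boundary inform the edge values.
* The widened endpoint stencil keeps the endpoint estimates exact for
  quadratics while suppressing their noise variance by ~q⁴ (q = stride);
  with a stride of 1 the two endpoint values alone would dominate the
  variance of the decision statistic.
* The moving-average halfwidth default (5 min) sits well below the
  slowest signal time constants (collapse ≈ 10 min, regrowth ≳ 20 min),
  so it suppresses channel noise without distorting the class-separating
  curvature.
* Degenerate inputs raise typed errors (absent overtone, empty window,
  degenerate baseline, non-uniform grid) instead of producing calls.

## Synthetic experiment generator

The generator emulates the screening assay end to end so the pipeline is
testable without an instrument: 20 min PBS baseline → 30 min bacteria in
medium under 30 µL/min flow → 15 min flush → 120 min static growth →
20 min second injection (phage or plain medium) → 15 min flush → 180 min
static incubation; 0.5-min sampling. Three scenarios: `control` (plain
medium), `infectious` (lytic, T7-like), `non_infectious` (adsorbing but
non-infecting, phi29-like at 2·10⁸ PFU/mL).

### Latent film state and kinetics

The latent state is (h, s, θ, m): effective film thickness (nm),
softness ∈ [0,1], fractional coverage, and rigidly coupled areal mass
(ng/cm²). Phase-wise kinetics, integrated with exact per-step updates
(exponential relaxation and logistic steps are closed-form, so the
integrator introduces no scheme error):

* adsorption: θ rises as a saturating exponential (k_a = 0.12/min,
  θ_max = 0.6) and h tracks it up to 40 nm;
* flow phases after adsorption strip 3% of θ and 6% of h as a
  front-loaded multiplicative transient (settled ≈ ⅔ into the phase), so
  the familiar flush dip is transient and the signal is already
  recovering when the flush ends;
* h grows logistically (r = 0.02/min, carrying thickness 150 nm) in all
  post-adsorption phases — fresh medium sustains growth under flow too;
* in phage scenarios, m rises toward the phage mass amplitude during the
  second injection with uptake rate proportional to titer
  (0.25/min at the 8·10⁷ PFU/mL reference);
* in the infectious scenario, one latent period (τ = 17 min, the T7
  lytic cycle) after the injection starts, an infected fraction p of the
  film relaxes (time constant 10 min) onto a debris layer
  (h_debris = 60 nm effective, s_debris = 0.4) while the surviving
  fraction (1−p) resumes logistic growth at 2.5× rate once the flow
  stops (the lysate that fuels regrowth is retained only in the static
  cell). Softness follows the thickness-weighted mixture of live (s = 1)
  and debris material.

### Infection fraction

p = 1 − exp(−(k_i · titer · exposure)^γ), with k_i = 7·10⁻⁷
mL·PFU⁻¹·min⁻¹ and γ = 0.6. With γ = 1 this is the single-hit Poisson
encounter model. The sublinear exponent is deliberate: a strictly linear
dose cannot simultaneously produce (i) a δD collapse that is nearly
independent of titer across a 200-fold range and (ii) survivor fractions
that differ by orders of magnitude between titers — yet both are
characteristic of a short-cycle lytic phage, whose burst progeny
amplify an initially small infected fraction while survivors remain
titer-graded. γ = 0.6 encodes that amplification (plus surface-limited
encounter kinetics) in closed form: at 20 min exposure the defaults give
p ≈ 0.94, 0.9994 and ≈1 at 4·10⁵, 2·10⁶ and 8·10⁷ PFU/mL, with survivor
fractions 6%, 6·10⁻⁴ and ≈0.

### Transduction and noise

Traces are the closed-form kernels applied to the latent state:

* ΔD_n = A_D · s · θ · δ_n(1 − e^(−h/δ_n))/δ₃, with A_D = 120 (10⁻⁶
  units) chosen so the peak ΔD₃ of a grown film is ≈39·10⁻⁶. This
  sensed-depth saturation kernel is a deliberately simple phenomenological
  surrogate for continuum (Voigt-type) viscoelastic modelling: it
  reproduces the overtone ordering, the growth of the overtone spread
  with film thickness, and its collapse on lysis, in closed form.
* Δf_n = −(n/C)·m + χ·A_f·θ·n/3, the Sauerbrey response to rigid phage
  load (C = sqrt(ρ_q·μ_q)/(2f₀²) ≈ 17.7 ng·cm⁻²·Hz⁻¹) plus a signed
  coupled-resonance term (A_f = 30 Hz) for discrete adhering bacteria,
  which can push Δf positive on some sensors.
* Per-sensor factors: sensitivity λ ~ lognormal(0, 0.15²) multiplying
  both channels (cancelled by the δD normalization, which is the point
  of the normalization) and resonance sign χ = ±1 with equal
  probability. Channel noise is i.i.d. Gaussian, 0.5 Hz on Δf and
  0.05·10⁻⁶ on ΔD — strong enough that classification is not trivially
  perfect on every replicate.

### Calibrated magnitudes

Two generator defaults are calibrated to the assay's characteristic
magnitudes rather than chosen freely: the phage mass amplitude
(≈356 ng/cm²) makes the noise-free Δf₃ step across the injection window
−60 Hz at the 8·10⁷ PFU/mL reference titer, and the debris state
(60 nm, s = 0.4) together with the 10-min collapse time places the
normalized δD drop at ≈0.80 for every titer (spread ≤ 0.05 across the
three defaults), while the phage-free control changes by < 1 Hz across
the same window.

### What the generator does not emulate

No spatial heterogeneity or microcolony structure, no filamentation, no
nutrient-depletion dynamics beyond the logistic carrying capacity, no
drift or 1/f instrument noise, and the non-infectious scenario omits the
transient dissipation dip seen when a high-titer phage suspension
transits the cell. Passing tests therefore demonstrate that the
detection procedure recovers lysis from traces with this statistical
structure (multiplicative sensor variability, additive channel noise,
titer-graded survivor regrowth); they do not certify performance on
instrument data with correlated drift or heterogeneous films.

## Default analysis problem sizes

The test suite and the acceptance script run the full pipeline at the
sizes a small screening study would use: single experiments of 800
samples × 5 overtones, an 8-replicate mixed panel for the separation
analysis, and a 50-replicate panel (25 infectious across the three
titers, 25 control/non-infectious) for the robustness statistics.

## Known limitations

* The dissipation kernel is phenomenological; it is not intended for
  extracting film moduli, and no Voigt/Kelvin-type fitting is provided.
* The coupled-resonance frequency term is linear in coverage with a
  random sign; real sensors show richer Δf phenomenology, which is why
  the detection statistic deliberately uses only ΔD.
* The classifier's decision statistic reduces (up to smoothing) to the
  difference of curve slopes at the window boundaries; signals whose
  post-flush dynamics are slower than the run remainder compress that
  margin. For phages with lytic cycles much longer than T7's 17 min the
  readout time and run length must be extended accordingly.
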