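# Methods

## Physical model

The skin simulant is a 10 mm silicone (PDMS) slab with conductivity
k = 0.23 W·m⁻¹·K⁻¹, diffusivity α = 12.8 × 10⁻⁸ m²·s⁻¹, emissivity 0.9 and
density 1350 kg·m⁻³ — within the reported range for human epidermis. It is
heated from below by a water-perfused plate and loses heat from its upper
surface to chamber air at 23.8 °C.

Steady states are solved on a thermal-resistance network of two
independent one-dimensional columns sharing the plate temperature:

* **undisturbed**: plate → slab conduction (R = L/k) → surface → combined
  convective/radiative boundary → air;
* **disturbed**: plate → slab → surface → contact resistance R_c → sensor
  node → top resistance R_t → boundary divided by an area factor A → air.

The boundary conductance is h = h_c + h_r with a flat-plate correlation
h_c = a·√v (a chosen so h_c ≈ 7 W·m⁻²·K⁻¹ at 0.2 m·s⁻¹ and ≈ 11 at
0.5 m·s⁻¹) and radiation linearized at the air temperature,
h_r = 4εσT³ ≈ 5.3 W·m⁻²·K⁻¹. Linearizing at a *fixed* temperature keeps
every node affine in the plate-to-air difference, so disturbance and bias
are exactly proportional to the surface-to-air gradient — the structural
property the analysis relies on. Series resistances carry a single flux, so
energy balance holds at every node by construction and the in-slab profile
is strictly linear, making the two-depth surface extrapolation exact on
noiseless data.

**Assumptions and what they exclude.** Lateral conduction between the
covered and bare sites is neglected (two independent columns) — the
simplest structure that reproduces the observed warming/cooling signs; no
evaporation or surface wetting is modelled; radiant temperature equals air
temperature; the sensor body is a single lumped node. The transient model
is single-pole relaxation per node with τ = L²/(π²α) ≈ 80 s (first
diffusion mode of the slab; a sensor's response time adds to its channel's
τ). Only minutes 21–29 of each 30-min step are analyzed, by which point the
relaxation residual is below 10⁻⁶ °C, so transient fidelity beyond
plausibility is not required. Runs where τ ≥ step_duration/3 carry a
warning flag.

## Coverage parameters

Six surface conditions are parameterized by (R_c, R_t, A), in m²·K·W⁻¹ for
the resistances:

| coverage | R_c | R_t | A | behaviour |
| --- | --- | --- | --- | --- |
| bare | 0 | 0 | 1.0 | reference |
| tape_only | 0.001 | 0.002 | 1.0 | slight warming |
| custom+tape | 0.003 | 0.001 | 1.0 | slight warming, least bias |
| grant+tape | 0.012 | 0.004 | 1.6 | cooling |
| ibutton+tape | 0.012 | 0.004 | 1.3 | warms at 0.5 m·s⁻¹, cools at 0.2 |
| ibutton_only | 0.012 | 0.002 | 1.7 | strongest cooling |

With A = 1 any added resistance shifts the surface node toward the plate
(warming); a fin-like area factor A > 1 lowers the effective above-surface
resistance below the bare boundary value (cooling); the taped iButton sits
between the two regimes, flipping sign with velocity because the bare
boundary resistance itself changes with velocity. The values were chosen
once so that the sign pattern and approximate magnitudes of the covered-
versus-bare differences match the benchtop observations (disturbances of
roughly +0.1 to −0.7 °C at an undisturbed surface of 31 °C, biases of a few
tenths for the thermally matched custom thermistor up to ≈ −2.3/−3.2 °C for
the un-taped iButton at 0.5 m·s⁻¹); they are conventional defaults, not
fitted quantities.

## Protocol defaults

Plate setpoints are derived by inverting the bare column so the
undisturbed surface spans gradients of 0–16 °C (0.5 m·s⁻¹) or 0–18 °C
(0.2 m·s⁻¹) over five equal steps of 30 min, sampled every 10 s. Embedded
reference thermistors sit at z₁ = 0.25 mm (the "directly subsurface"
reference; the physical description bounds it only as within 1 mm) and
z₂ = 5 mm (unstated in the source protocol; both are explicit `RigConfig`
fields). With these depths and the default flux regime the two-depth
location corrections across the full design span ≈ 0.00–0.32 °C, inside
the reported 0.00–0.39 °C envelope.

Measurement model: observation = truth × gain + offset + N(0, σ), then
quantization to the logger resolution. Defaults: embedded thermistors
σ = 0.005 °C at 0.01 °C resolution; custom and Grant thermistors
σ = 0.01 °C at 0.01 °C; iButtons σ = 0.02 °C at their native 0.0625 °C
resolution. These keep every channel's steady-window SD under the 0.05 °C
qualification gate while remaining realistic for the logger class.

## Analysis choices

* **Steady-state window** [21, 29) min of each step, half-open (the source
  quotes "minutes 21–29" without a boundary convention); the SD < 0.05 °C
  gate applies to every analyzed channel of the run.
* **Surface correction** is applied to the embedded reference channels
  only, never to the surface sensor — matching how such sensors are used.
* **Matching** of covered to bare states is by (velocity, replicate, step)
  when the bare replicate exists, otherwise by linear interpolation of the
  bare surface temperature against plate setpoint within that velocity.
  A velocity with no bare run is an error.
* **Gradient** is defined as undisturbed surface minus ambient.
* **Fixed-point summaries** (the 31 °C table): the published table does not
  state its computation; here each replicate's bias is fitted linearly
  against the sensor reading across the five steps and evaluated at 31 °C
  (for disturbance, against the undisturbed surface temperature), then
  replicates are summarized as mean ± t-based unadjusted 95 % CI with
  df = n − 1. This choice is recorded in the results metadata.
* **Calibration**: 8-min steady windows where the reference SD < 0.007 °C,
  greedy earliest-first, at most one window per plateau (plateau means
  separated by > 0.5 °C); the stability gate applies to the reference only,
  sensor stability is recorded but not gated. The reference is regressed on
  the raw means and the line inverted, so `corrected = (raw − offset)/gain`
  maps readings onto the reference scale.
* **Inter-sensor anchors**: the seven anchor temperatures average the
  per-sensor predictions of the individual custom-thermistor fits (the
  aggregation across the five custom sensors is not specified in the source
  description; the choice is recorded in output metadata). Human-trial
  differences use four-site weighted means while model differences use
  single sensors — an asymmetry preserved deliberately, since rig
  conditions are far less variable than skin sites.
* **Vapor pressure** uses the Magnus form
  e = (RH/100)·0.61094·exp(17.625·T/(T + 243.04)) kPa; the constants live
  in one place so an alternative correlation can be substituted.
* **Sweat onset**: "distinct increase > 0.5 kPa" is operationalized as a
  rise above the mean of the final 3 pre-exercise minutes, sustained for at
  least 60 s; both the sustain requirement and baseline window are
  arguments. The earliest of the four sites is the participant's onset, and
  the participant-specific pre-sweating summary window is the 3 min
  immediately preceding it.

## Human-trial generator

Fourteen participants by default: per-site baselines (chest 33.5, arm
32.5, thigh 32.0, leg 31.5 °C) with participant- and site-level normal
offsets, a brief vasoconstriction dip then saturating rise of 0.8–1.5 °C
during 45 min of cycling, exponential recovery afterwards; sensor-type
offsets (default custom 0, Grant −0.15, iButton +0.20 °C) and 0.05 °C
noise; absolute vapor pressure at each site steps up by 0.6 kPa at an
onset drawn uniformly 4.8–10.3 min after exercise start (the reported
onset range). The generator reproduces the *statistical structure* the
analysis assumes — trends, offsets, noise, an onset step — not real skin:
no site-to-site covariance from shared perfusion, no movement artifacts,
no tape wetting. Passing tests therefore validate the machinery, not
in-vivo accuracy of any particular sensor.

## Problem sizes and determinism

The default design (60 runs × 5 steps × 180 samples × ~6 channels) runs in
about two seconds; Monte-Carlo suites use 400–1000 repetitions. All
stochastic outputs flow from explicit integer seeds; suite-level runs
derive per-run seeds from a master seed via a seed sequence, so a fixed
master seed reproduces every table bit-for-bit.

## Known limitations

One-dimensional columns cannot represent edge effects of finite sensor
footprints; the area-factor fin model is a lumped caricature of conjugate
convection around a sensor body; coverage parameters are plausible
defaults, not measured properties of specific commercial devices; the
linearized radiation slightly underestimates losses at the hottest steps
(< 2 % of h_r over the protocol range); and the human-trial generator's
independence assumptions make its confidence intervals somewhat
conservative relative to real repeated-measures data.
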