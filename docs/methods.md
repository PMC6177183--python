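# Methods

`cgmdyn` analyses continuous glucose monitoring (CGM) experiments in
which sensors placed at different sites — four intraperitoneal (IP)
quadrants and two subcutaneous (SC) positions — respond to intravenous
glucose challenges while arterial glucose is sampled as the reference.
The pipeline has five stages: synthetic experiment generation,
preprocessing, model identification, inclusion/metrics, and
mixed-effects site comparison. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Sensor dynamics model

The combined physiological-plus-sensor dynamics between arterial
glucose G_IA and sensed glucose G_sens are modelled as first order with
dead time:

    dG_sens(t)/dt = ( K · G_IA(t − Θ) − G_sens(t) ) / τ

with gain K (dimensionless; sensors are analysed uncalibrated, so K is
an arbitrary positive scale), time constant τ (s) and pure delay Θ (s).
All simulation and identification use the exact discretization of this
ODE on a 1 s grid with the input held constant per cell:

    y[k+1] = a·y[k] + (1 − a)·K·u[k − Θ],   a = exp(−Δt/τ).

A unit test checks this recursion against an adaptive ODE integration
to < 1e−6 mmol/L.

## Synthetic experiments

The generator emulates one experiment day per pig: a glucose clamp
(90 min, target rise 5 mmol/L) followed by two IV meals (245 mg/kg body
weight infused over 30 min), with a 30 min lead-in and recovery gaps.
Defaults: 12 pigs, 6 sensors each.

**Arterial disposal.** Arterial glucose is not the object of study, so a
minimal one-pool model stands in:

    dG/dt = −k_cl·(G − G_basal) + u(t) / (V_d · 0.18016)

where u is the infusion rate in mg/kg/s, V_d = 150 mL/kg the glucose
distribution volume, 180.16 g/mol the molar mass, G_basal = 5.0 mmol/L,
and k_cl = 9.0e−4 s⁻¹ (glucose half-life ≈ 13 min, plausible under
anaesthesia). k_cl was set once so that the standard meal produces a
rise of ≈ 4.5 mmol/L; the test suite asserts the rise lies in the design
band 3.5–5.5 mmol/L rather than hard-coding the calibration. The clamp
is emulated by a stand-in plateau-holding profile (10 min priming ramp,
then the rate that balances clearance); no closed-loop controller is
modelled, because only the shape of a sustained elevation matters
downstream.

**Sensor sampling.** The transmitted sensor value updates only on
one-minute boundaries (zero-order hold of the dense solution); reads
occur at gaps uniform in [20, 22] s. Measurement noise is
glucose-dependent with the worst-case ISO 15197:2013 variance: SD
0.83/2 mmol/L for G ≤ 5.55 mmol/L and (0.15/2)·G above. Outliers
(probability 0.01/sample, offset ±1–3 mmol/L uniform, random sign —
the magnitude distribution is a package choice, as transmission noise
has no published distribution) and dropouts (probability 0.01) complete
the raw stream. Peritoneal-fluid samples are the sensed truth plus
analyser noise; optional cold-storage drift adds N(+0.1, 0.1) mmol/L
per sample. Arterial samples are exact values of the pool solution on a
schedule that is dense (30 s) around challenges and sparse (3–10 min)
elsewhere, always including the four baseline slots at 0/−5/−10/−15 min.

**Per-site truth.** Ground-truth (K, τ, Θ) are drawn per sensor around
site-level means (delays ≈ 146–204 s for IP quadrants, 241 s for SC;
time constants 8.6–15.6 min IP, 9.5 min SC) with a between-pig delay
offset (SD 50 s) and per-sensor scatter (SD 60 s; τ lognormal with 30%
relative SD, truncated to [60, 1800] s; K uniform in [0.6, 1.4]).
Element orientation (toward the abdominal wall vs toward the viscera)
is drawn at random per IP sensor, as placement effectively randomizes
it; making it deterministic per quadrant would confound it with site.

All randomness flows from a single master seed through named
`SeedSequence` substreams (per pig, per sensor), so any part of a study
is reproducible in isolation.

**What the generator does not emulate.** No insulin action or
endogenous production dynamics, no direction-dependent (rise vs fall)
sensor asymmetry, no slow sensor drift or biofouling, no
device-communication artefacts beyond i.i.d. outliers/dropouts.
Passing tests therefore demonstrate correctness of the estimation
machinery under the declared noise model, not robustness to every
artefact of animal data.

## Preprocessing

1. **Median filter**, window 5 samples (~130 s at the read cadence),
   removes single-sample outliers; edges use shrunken windows,
   timestamps are untouched.
2. **Kalman smoother** on a central-remote rate model with states
   (central glucose g_c, its rate r, remote glucose g_r), where
   ġ_c = r, ṙ = white noise, ġ_r = (g_c − g_r)/T_d with diffusion time
   T_d = 600 s. The measurement is the remote state with the ISO 15197
   variance of the raw value (the ≤ branch applies at exactly
   5.55 mmol/L). Initial covariance is the identity; the initial state
   is the first measurement with zero rate. Fixed-interval smoothing
   (forward filter + RTS pass) on the 1 s grid yields the mean, its
   posterior SD, and a model-consistent rate estimate
   ġ_r = (g_c − g_r)/T_d (in mmol/L/min).

   *Process-noise units.* The source material for the smoother settings
   prints a partially garbled process-noise matrix ("variance Δt per
   step" on the rate state). Read in per-second units this permits rate
   jumps of 1 mmol/L/s — three orders of magnitude above physiological
   rates — and the filter barely smooths. The smoothing method this
   stage follows formulates its state space in minutes, so the package
   adopts the minute-unit reading: unit spectral density in
   (mmol/L/min)²/min, i.e. 1/60³ (mmol/L/s)²/s after per-second (Van
   Loan) discretization. With it the smoother reduces the RMSE against
   truth about four-fold and the identification below attains the
   Cramér–Rao bound (see *Identifiability*).

   *Transmit-hold handling.* Because the device refreshes its
   transmitted value only once per minute, reads within one hold window
   are repeated measurements of the last update instant; the smoother
   reassigns each read to the preceding minute boundary (configurable;
   `hold_period=None` keeps raw timestamps). Without this, the hold
   injects a systematic ≈ +30 s delay bias.

   *Outlier pass.* After a first smoothing pass, measurements whose
   residual against the smoothed mean exceeds 3 × the posterior
   residual SD, sqrt(P_smoothed + R), are removed and the stream is
   re-smoothed once. The residual SD (not the latent-mean SD alone) is
   the correct yardstick: the latent-mean SD is smaller than the
   measurement noise itself and would strip several percent of clean
   points. Grid points further than 90 s from any surviving measurement
   are reported as explicit NaN gaps; windows with > 10% gaps are
   rejected downstream rather than imputed.
3. **Arterial interpolation.** Sparse arterial samples are brought to
   the 1 s grid by a shape-preserving piecewise-cubic Hermite
   interpolant (monotone, no overshoot past local extrema), evaluated
   only inside the sample span.

## Identification

Per recording × challenge, both series are baseline-subtracted: the
arterial baseline is the mean of the samples at 0/−5/−10/−15 min before
challenge start (each slot matched within ±90 s), the sensor baseline
the mean of the smoothed series over the final 3 min. The window runs
from challenge start to 15 min before the next challenge (or series
end); windows shorter than 600 s are rejected.

Delays 0–900 s are scanned at 1 s steps. At fixed delay, the time
constant is found by a bounded scalar search on log τ over [10, 7200] s
(tolerance 1e−8 on log τ) with the gain solved in closed form by least
squares; the delay with the smallest output MSE wins, ties broken
toward the smaller delay. This time-domain output-error formulation
reaches the same optimum as a frequency-domain transfer-function fit
for a first-order SISO model with fixed delay, and is transparent and
directly testable. NaN gaps are excluded pairwise from the residual sum.
Goodness of fit is the normalized-RMSE percentage
100·(1 − ‖y−ŷ‖₂/‖y−ȳ‖₂) (the standard fit output of transfer-function
estimation tools; may be negative).

**Identifiability.** With worst-case ISO noise, one-minute value
updates, and a 245 mg/kg/30 min meal, the Fisher information for Θ in a
single challenge window (~5400 s) gives a Cramér–Rao SD of ≈ 42 s for
joint (K, τ, Θ) estimation — the smooth meal input makes delay and time
constant strongly confounded. The smoothed-series fit attains this
bound (median |Θ̂ − Θ| ≈ 28 s over replicates; fitting raw per-minute
averages instead gives ≈ 96 s). Noiseless recovery is exact on the
delay grid with τ and K to < 0.1%. Clamp challenges, whose priming ramp
is steeper, identify the delay several-fold more precisely than meals.

## Inclusion and metrics

A recording enters the statistics only if (1) the smoothed rate stays
strictly below 0.1 mmol/L/min in absolute value at every grid second of
the 3 min pre-challenge window, and (2) the model fit exceeds 70%
strictly; the recorded exclusion reason is the first failing criterion
in that order (a missing window is its own category, `window_gap`).

Model-free metrics, computed on smoothed IV-meal responses only
(clamps feed identification only): time to 50% of the window maximum
above baseline and time to 50% return toward baseline after the peak,
both in minutes from challenge start, with the crossing refined by
linear interpolation between grid seconds. The half-rise of a pure
first-order step equals (Θ + τ·ln 2)/60 min, which the tests verify.
If the peak never exceeds baseline or the signal never declines to
half, the metric is flagged undefined rather than invented.

**Sensor-vs-fluid delay.** The delay of a sensor behind its local
peritoneal-fluid samples is estimated by scanning d in [0, 600] s and
fitting the one-step ARX(1,1) model y[k] = a·y[k−1] + b·u[k−d] by least
squares, minimizing the prediction-error sum of squares (ties toward
smaller d), after interpolating the fluid samples with the same
monotone interpolant. The input gain is constrained to b ≥ 0: sensor
and fluid track the same glucose, so the steady-state gain is positive;
without the constraint, spurious trend-correcting fits (a > 1, b < 0)
at large delays can out-score the physical solution on smooth series.
Fluid series rising less than 0.5 mmol/L over the challenge are flagged
uninformative and excluded from delay summaries.

**Cohort normalization.** Baseline-subtracted, challenge-aligned curves
are averaged pointwise; the mean is scaled affinely to [0, 1] and the
identical scale applied to every curve before the SD band is computed.

**Diffusion time.** The worked example t = x²/(2D) with
D = 6.7e−6 cm²/s gives ≈ 746 s for x = 1 mm — the physical floor under
fluid-phase peritoneal glucose sensing.

## Statistics

Each dynamic parameter (Θ, τ, t50max, t50decline) is analysed with a
linear mixed model fitted by maximum likelihood: fixed effects for
site, fluid regimen and (IP-only models) element orientation; a random
intercept per pig. Contrasts are the six IP-quadrant pairs (from the
IP-only 4-level model) and pooled IP vs SC (from a binary-location
model on all records). Each contrast is tested with a t-statistic whose
degrees of freedom come from the Satterthwaite approximation,
df = 2v²/Var(v̂), where v is the contrast variance as a function of the
two variance components and Var(v̂) follows by the delta method from
the observed information of the profile log-likelihood (computed in
closed form via the Woodbury identity; derivatives by central
differences). Estimation is delegated to statsmodels MixedLM, with a
direct Nelder–Mead maximization of the profile likelihood as a fallback
for boundary fits where the pig variance collapses to zero (such fits
are flagged singular and fall back to the classical residual df). The
implementation is cross-checked against lmerTest (R) in the test suite
and agrees to ~3 decimals in df and p.

The significance threshold is fixed at α = 0.01 as the study's own
multiplicity convention; no further correction is applied. Type-I
calibration is verified by simulation (500 null studies at 8-pig
scale: empirical rate within [0.005, 0.02]); power and unbiasedness by
injecting a +70 s SC-vs-IP delay effect at 12-pig scale.

The stats stage also ships a direct cohort generator
(`simulate_metrics_table`) that draws included-record tables as
site mean + pig intercept (SD 50 s) + residual (SD 100 s for delays),
bypassing the signal pipeline, so distributional properties of the
tests can be simulated cheaply. The residual SD is a package choice:
published delay scatter (~±140 s) mixes site effects, pig effects and
replicate error, and ~100 s within-pig, within-site scatter is the
realistic decomposition.

## Problem sizes in the shipped checks

The test suite runs the full pipeline on 2-pig studies, parameter
recovery on 50 single-meal replicates, and statistical calibration on
500 simulated 8-pig studies with 12-replicate power checks at 12-pig
scale; the analysis drivers default to the full 12-pig layout. These
sizes are the package's own choices for routine verification;
`analysis/01_simulate.py --pigs N` scales the study arbitrarily.

## Known limitations

- The delay estimate from a single meal is information-limited (see
  *Identifiability*); site-level comparisons inherit ~40 s per-recording
  scatter beyond biological variability.
- One symmetric first-order model is fitted per recording; rise/fall
  asymmetry is deliberately out of scope.
- The clamp profile is a stand-in, not a feedback controller; clamp
  plateaus are less variable than real clamps.
- Sensor calibration against reference glucose is deliberately absent
  (uncalibrated recordings are the object of analysis), so gains K are
  comparable only in distribution, not in value.
- Oscillating recordings are not classified as artefact vs physiology;
  they simply fail the stability or fit criterion.
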