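# cgmdyn

Dynamics of continuous glucose monitoring (CGM) sensors at alternative
sensing sites, estimated from intravenous glucose challenges.

An artificial pancreas needs glucose measurements that track blood
quickly. Subcutaneous (SC) CGM carries minutes of transport lag plus
the sensor's own dynamics; the peritoneal cavity is a candidate site
with potentially faster kinetics. `cgmdyn` implements the complete
analysis for animal experiments that compare intraperitoneal (IP) and
SC sensing: preprocessing of raw sensor streams, identification of a
first-order-plus-dead-time model per glucose challenge, inclusion
criteria and model-free response metrics, and a mixed-effects
comparison of sensing sites. Because such animal datasets are not
public, the package includes a first-class synthetic-experiment
generator with known ground truth, so every stage is testable end to
end.

## The model

The combined tissue-plus-sensor dynamics between intra-arterial glucose
G_IA and the sensed glucose G_sens are modelled as

    dG_sens(t)/dt = ( K · G_IA(t − Θ) − G_sens(t) ) / τ

with gain K, time constant τ and pure time delay Θ. Per recording and
challenge, the pipeline

1. denoises the raw irregular stream (5-sample median filter, then a
   fixed-interval Kalman smoother on a central–remote rate model,
   T_d = 600 s, ISO 15197 worst-case measurement variance), producing a
   uniform 1 s series with a ±SD band and a rate estimate;
2. interpolates sparse arterial samples to 1 s with a shape-preserving
   cubic;
3. subtracts per-challenge stationary baselines (arterial: mean of the
   samples at 0/−5/−10/−15 min; sensor: last 3 min of smoothed data);
4. scans delays 0–900 s at 1 s resolution, solving (K, τ) by
   output-error least squares at each delay, and keeps the delay with
   the lowest MSE;
5. includes a recording only if the pre-challenge rate stays strictly
   under 0.1 mmol/L/min and the fit percentage
   100·(1 − ‖y−ŷ‖/‖y−ȳ‖) exceeds 70%;
6. computes time to 50% of maximum and time to 50% return to baseline
   on IV-meal responses, plus sensor-vs-fluid delays (ARX(1,1) grid
   scan) and the cohort normalization to [0, 1];
7. compares sites with linear mixed models (random pig intercept, ML)
   and Satterthwaite t-tests at α = 0.01 — the six IP-quadrant pairwise
   contrasts and pooled IP vs SC.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate.py --seed 1     # 12 pigs, clamp + 2 IV meals
python analysis/02_preprocess.py            # median filter + Kalman smoother
python analysis/03_identify.py              # delay-model fits per recording
python analysis/04_metrics.py               # inclusion + dynamic metrics
python analysis/05_compare.py               # mixed-model site contrasts
```

With seed 1 this prints, along the way:

```
meal arterial rises span [4.41, 4.44] mmol/L (design band 3.5-5.5)
72 sensors smoothed; median RMSE 0.160 mmol/L (raw 0.621); median 2SD coverage 95.24%
216 recordings x challenges; 216 fitted
median |theta_hat - theta| = 57 s; median fit = 88.2%
187 of 216 recordings included
sensor-vs-fluid delays: 0-234 s (mean 9 s) over 48 comparisons
diffusion worked example: 1 mm in water takes 746 s
```

and finally the per-site summary (mean ± SD of delay, time constant,
fit %, and the two half-times) with the contrast table. In this
realisation the pooled IP-vs-SC delay contrast comes out at
−54.8 ± 19.8 s (Satterthwaite df 184, p = 0.0062): IP sensors lead SC
sensors, consistent with the ≈ 70 s site difference the generator
planted minus per-recording estimation scatter. The smoothing halves
to quarters the raw noise, fit percentages average ~88%, and 46 of the
48 sensor-vs-fluid delay estimates are ≤ 2 s — the sensor's internal
lag is negligible against the physiological blood-to-peritoneum
dynamics. The delay summary per site carries an SD above 100 s: with a
30-min meal infusion, worst-case meter-grade noise and one-minute
transmitted-value updates, a single challenge simply does not carry
more delay information (see the identifiability discussion in
`docs/methods.md`). All tables land in `results/`.

The `cgmdyn` command exposes the same stages for user-supplied CSV data
(`simulate`, `preprocess`, `identify`, `metrics`, `compare`, `report`,
`run`); series files are plain CSV with a `time_s,glucose_mmol_l`
header.

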