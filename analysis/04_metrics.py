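#!/usr/bin/env python
"""Apply the inclusion criteria (pre-challenge stability < 0.1 mmol/L/min
and model fit > 70%, both strict) and compute the model-free dynamic
metrics: time to 50% of maximum and time to 50% return to baseline
(IV meals only), the sensor-vs-fluid delays, the cohort normalization
and the diffusion worked example.

Writes results/metrics.csv, results/fluid_delays.csv and
results/normalized_cohort.csv.
"""
from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cgmdyn import io as cio
from cgmdyn import metrics as cmetrics
from cgmdyn.pipeline import identification_windows, metrics_experiment
from cgmdyn.types import is_ip

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "scratch" / "study")
    args = ap.parse_args()

    study = cio.load_study(args.study / "manifest.yaml")
    models = pd.read_csv(ROOT / "results" / "models.csv")

    tables, delays, curves = [], [], {"IP": [], "SC": []}
    for exp in study.experiments:
        smoothed = {}
        for rec in exp.sensors:
            path = args.study / "smoothed" / f"{exp.pig_id}_{rec.dyn.site}.csv"
            smoothed[rec.dyn.site] = cio.read_smoothed_series(path, rec.raw.meta)
        sub = models[models["pig_id"] == exp.pig_id]
        tab = metrics_experiment(exp, smoothed, sub)
        tables.append(tab)

        # sensor-vs-fluid delay per IP site
        for site, fluid in exp.fluid_samples.items():
            try:
                d = cmetrics.estimate_sensor_fluid_delay(smoothed[site], fluid)
                delays.append(dict(pig_id=exp.pig_id, site=site, delay_s=d))
            except ValueError:
                delays.append(dict(pig_id=exp.pig_id, site=site, delay_s=None))

        # challenge-aligned curves of the first meal for the cohort figure
        meal = next((w for w in identification_windows(
            exp.events, exp.arterial_truth.times[-1]) if w[0].kind == "meal"),
            None)
        if meal is not None:
            _, t0, t_end = meal
            n = int(min(t_end - t0, 4500))
            for rec in exp.sensors:
                sm = smoothed[rec.dyn.site]
                m = (sm.times >= t0) & (sm.times < t0 + n)
                row = tab[(tab["site"] == rec.dyn.site)
                          & (tab["challenge_kind"] == "meal")]
                if m.sum() == n and len(row) and row.iloc[0]["included"]:
                    base = row.iloc[0]["g_sens_stat"]
                    curves["IP" if is_ip(rec.dyn.site) else "SC"].append(
                        sm.mean[m] - base)

    out_dir = ROOT / "results"
    metrics_table = pd.concat(tables, ignore_index=True)
    metrics_table.to_csv(out_dir / "metrics.csv", index=False)
    pd.DataFrame(delays).to_csv(out_dir / "fluid_delays.csv", index=False)

    norm_rows = []
    for loc, series in curves.items():
        if not series:
            continue
        nc = cmetrics.normalize_cohort(series)
        step = 60  # one point per minute keeps the file small
        for i in range(0, len(nc.times), step):
            norm_rows.append(dict(location=loc, t_s=nc.times[i],
                                  mean=nc.mean[i], sd=nc.sd[i]))
    pd.DataFrame(norm_rows).to_csv(out_dir / "normalized_cohort.csv",
                                   index=False)

    inc = metrics_table["included"]
    print(f"{inc.sum()} of {len(metrics_table)} recordings included")
    print(metrics_table.groupby("exclusion_reason").size().to_string())
    dl = pd.DataFrame(delays)["delay_s"].dropna()
    if len(dl):
        print(f"sensor-vs-fluid delays: {dl.min():.0f}-{dl.max():.0f} s "
              f"(mean {dl.mean():.0f} s) over {len(dl)} comparisons")
    t_diff = cmetrics.diffusion_time(0.1, 6.7e-6)
    print(f"diffusion worked example: 1 mm in water takes {t_diff:.0f} s")


if __name__ == "__main__":
    main()
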