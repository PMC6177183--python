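"""CSV/YAML persistence for series, experiments and study manifests.

Series files are plain CSV with header ``time_s,glucose_mmol_l``; raw
sensor and sparse files may add a ``flag`` column (ok|outlier|dropout)
that only synthetic-truth bookkeeping writes and the analysis path never
reads. Smoothed series add ``sd_mmol_l,rate_mmol_l_min`` columns. The
study manifest is YAML and records pigs, events, sensor metadata, file
paths and (for synthetic studies) the ground-truth dynamics.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Experiment, SensorRecord, Study, StudyConfig
from .types import (
    InfusionEvent,
    SensorMeta,
    SensorSeries,
    Series,
    SmoothedSeries,
    TrueDynamics,
)

SERIES_HEADER = ["time_s", "glucose_mmol_l"]


def write_series(series: Series | SensorSeries | SmoothedSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(series, SmoothedSeries):
        df = pd.DataFrame({
            "time_s": np.round(series.times, 3),
            "glucose_mmol_l": np.round(series.mean, 6),
            "sd_mmol_l": np.round(series.sd, 6),
            "rate_mmol_l_min": np.round(series.rate, 6),
        })
    else:
        df = pd.DataFrame({
            "time_s": np.round(series.times, 3),
            "glucose_mmol_l": np.round(series.values, 6),
        })
        if isinstance(series, SensorSeries) and series.flags is not None:
            df["flag"] = series.flags
    df.to_csv(path, index=False)


def read_series(path: str | Path) -> Series:
    """Read a series CSV; rejects malformed rows and non-monotone times."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"{path}: unreadable CSV ({e})") from e
    missing = [c for c in SERIES_HEADER if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing expected columns {missing}; header must contain "
            f"{SERIES_HEADER}"
        )
    t = pd.to_numeric(df["time_s"], errors="coerce")
    v = pd.to_numeric(df["glucose_mmol_l"], errors="coerce")
    bad = np.flatnonzero(t.isna() | (v.isna() & df["glucose_mmol_l"].notna()))
    if bad.size:
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    return Series(t.to_numpy(), v.to_numpy())


def read_sensor_series(path: str | Path, meta: SensorMeta | None = None) -> SensorSeries:
    s = read_series(path)
    return SensorSeries(s.times, s.values, meta=meta or SensorMeta())


def read_smoothed_series(path: str | Path, meta: SensorMeta | None = None) -> SmoothedSeries:
    df = pd.read_csv(path)
    for c in ("time_s", "glucose_mmol_l", "sd_mmol_l", "rate_mmol_l_min"):
        if c not in df.columns:
            raise ValueError(f"{path}: smoothed series requires column {c!r}")
    return SmoothedSeries(df["time_s"].to_numpy(float),
                          df["glucose_mmol_l"].to_numpy(float),
                          df["sd_mmol_l"].to_numpy(float),
                          df["rate_mmol_l_min"].to_numpy(float),
                          meta=meta or SensorMeta())


# -- study persistence ------------------------------------------------------

def _event_dict(e: InfusionEvent) -> dict:
    return {"kind": e.kind, "t_start": float(e.t_start),
            "duration": float(e.duration), "dose": float(e.dose)}


def write_study(study: Study, out_dir: str | Path) -> Path:
    """Persist a synthetic study: per-pig series files plus manifest.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pigs = []
    for exp in study.experiments:
        pdir = out / exp.pig_id
        write_series(exp.arterial_truth, pdir / "arterial_truth.csv")
        write_series(exp.arterial_samples, pdir / "arterial_samples.csv")
        sensors = []
        for rec in exp.sensors:
            site = rec.dyn.site
            write_series(rec.raw, pdir / f"sensor_{site}.csv")
            write_series(rec.truth, pdir / f"sensor_{site}_truth.csv")
            sensors.append({
                "site": site,
                "orientation": rec.dyn.orientation,
                "fluid_regimen": rec.dyn.fluid_regimen,
                "file": f"{exp.pig_id}/sensor_{site}.csv",
                "truth_file": f"{exp.pig_id}/sensor_{site}_truth.csv",
                "true_K": rec.dyn.K, "true_tau": rec.dyn.tau,
                "true_theta": rec.dyn.theta,
            })
        fluid = {}
        for site, fs in exp.fluid_samples.items():
            write_series(fs, pdir / f"fluid_{site}.csv")
            fluid[site] = f"{exp.pig_id}/fluid_{site}.csv"
        pigs.append({
            "pig_id": exp.pig_id,
            "body_mass_kg": exp.body_mass,
            "events": [_event_dict(e) for e in exp.events],
            "arterial_truth": f"{exp.pig_id}/arterial_truth.csv",
            "arterial_samples": f"{exp.pig_id}/arterial_samples.csv",
            "sensors": sensors,
            "fluid_samples": fluid,
        })
    manifest = {"seed": study.seed, "n_pigs": len(study.experiments), "pigs": pigs}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "manifest.yaml"


def load_study(manifest_path: str | Path) -> Study:
    """Reload a study written by :func:`write_study`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)
    exps = []
    for pig in man["pigs"]:
        events = [InfusionEvent(**e) for e in pig["events"]]
        sensors = []
        for s in pig["sensors"]:
            meta = SensorMeta(pig_id=pig["pig_id"], site=s["site"],
                              orientation=s["orientation"],
                              fluid_regimen=s["fluid_regimen"],
                              sensor_id=f"{pig['pig_id']}_{s['site']}")
            raw = read_sensor_series(root / s["file"], meta)
            truth = read_series(root / s["truth_file"])
            dyn = TrueDynamics(K=s["true_K"], tau=s["true_tau"],
                               theta=s["true_theta"], site=s["site"],
                               orientation=s["orientation"],
                               fluid_regimen=s["fluid_regimen"])
            sensors.append(SensorRecord(dyn, raw, truth))
        fluid = {site: read_series(root / p)
                 for site, p in pig.get("fluid_samples", {}).items()}
        exps.append(Experiment(
            pig_id=pig["pig_id"], body_mass=pig["body_mass_kg"], events=events,
            arterial_truth=read_series(root / pig["arterial_truth"]),
            arterial_samples=read_series(root / pig["arterial_samples"]),
            sensors=sensors, fluid_samples=fluid,
        ))
    cfg = StudyConfig(n_pigs=len(exps), events=list(exps[0].events),
                      t_end=float(exps[0].arterial_truth.times[-1]))
    return Study(cfg, int(man.get("seed", 0)), exps)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
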