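"""Synthetic intravenous-glucose experiments with known sensor dynamics.

Generates the full layout of an animal CGM experiment: a glucose clamp
followed by two IV meals (245 mg/kg over 30 min), arterial glucose from a
one-pool disposal model, six sensors per pig (four intraperitoneal, two
subcutaneous) whose dense responses obey the first-order-plus-dead-time
model

    dG_sens/dt = (K * G_IA(t - theta) - G_sens) / tau

solved by exact discretization, irregular 20-22 s sampling of one-minute
held values, glucose-dependent (ISO 15197 worst-case) measurement noise,
occasional outliers/dropouts, and sparse arterial/fluid reference samples.

Every stage draws from named substreams of one master seed, so any pig or
sensor is reproducible in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .types import (
    IP_SITES,
    SC_SITES,
    InfusionEvent,
    NoiseConfig,
    SensorMeta,
    SensorSeries,
    Series,
    TrueDynamics,
    is_ip,
    validate_events,
)

#: glucose molar mass, g/mol; converts mg/kg doses to mmol/L via V_d
GLUCOSE_MOLAR_MASS = 180.16


@dataclass(frozen=True)
class DisposalParams:
    """One-pool arterial disposal: dG/dt = -k_cl (G - G_basal) + u/(V_d * 0.18016).

    Defaults are calibrated once so the standard 245 mg/kg / 30 min meal
    produces a rise of about 4.5 mmol/L (within the 3.5-5.5 mmol/L band).
    """

    G_basal: float = 5.0   # mmol/L
    V_d: float = 150.0     # mL/kg
    k_cl: float = 9.0e-4   # 1/s

    def __post_init__(self) -> None:
        if not (3.0 <= self.G_basal <= 8.0):
            raise ValueError("G_basal must lie in [3, 8] mmol/L")
        if self.V_d <= 0 or self.k_cl < 0:
            raise ValueError("V_d must be > 0 and k_cl >= 0")


def _rate_to_conc(rate_mg_kg_s: np.ndarray, V_d: float) -> np.ndarray:
    """mg/kg/s infusion -> mmol/L/s concentration inflow."""
    return np.asarray(rate_mg_kg_s) / (V_d * GLUCOSE_MOLAR_MASS / 1000.0)


def _conc_to_rate(conc_mmol_l_s: float, V_d: float) -> float:
    return conc_mmol_l_s * (V_d * GLUCOSE_MOLAR_MASS / 1000.0)


#: ramp-up time used for the plateau-holding clamp profile
CLAMP_PRIME_S = 600.0


def make_infusion_profile(
    events: list[InfusionEvent],
    grid_dt: float = 1.0,
    t_end: float | None = None,
    disposal: DisposalParams | None = None,
) -> Series:
    """Infusion-rate series (mg/kg/s) on a uniform grid starting at t = 0.

    Meals and boluses infuse dose/duration inside their window (the
    integral over the window equals the dose to rounding error). Clamps
    emit a stand-in plateau-holding profile: a priming ramp over the
    first 10 min that lifts glucose by the target rise, then the rate
    that balances clearance at the plateau under ``disposal``.
    """
    validate_events(events)
    disposal = disposal or DisposalParams()
    if t_end is None:
        t_end = max((e.t_end for e in events), default=0.0) + grid_dt
    n = int(np.ceil(t_end / grid_dt))
    times = np.arange(n) * grid_dt
    rate = np.zeros(n)
    for ev in events:
        if ev.kind in ("meal", "bolus"):
            dur = ev.duration if ev.duration > 0 else grid_dt
            r = ev.dose / dur
            # overlap fraction of each grid cell [t_i, t_i + dt) with the window
            lo = np.clip((ev.t_start - times) / grid_dt, 0.0, 1.0)
            hi = np.clip((ev.t_start + dur - times) / grid_dt, 0.0, 1.0)
            rate += r * (hi - lo)
        else:  # clamp: dose is the target rise in mmol/L
            rise = ev.dose
            hold = _conc_to_rate(disposal.k_cl * rise, disposal.V_d)
            prime = _conc_to_rate(rise / CLAMP_PRIME_S, disposal.V_d)
            t_rel = times - ev.t_start
            in_prime = (t_rel >= 0) & (t_rel < CLAMP_PRIME_S)
            in_hold = (t_rel >= 0) & (t_rel < ev.duration)
            rate += hold * in_hold + prime * in_prime
    return Series(times, rate)


def simulate_arterial(
    profile: Series,
    disposal: DisposalParams | None = None,
    seed: int | np.random.Generator = 0,
    events: list[InfusionEvent] | None = None,
) -> tuple[Series, Series]:
    """Dense (grid of ``profile``) and sparse-sampled arterial glucose.

    The pool is solved by exact discretization of the linear ODE with the
    infusion held constant over each grid cell. Sparse samples emulate
    manual blood-gas analysis: every 30 s around challenge onsets and
    during challenges, at intervals up to 10 min elsewhere, and always at
    t0, t0-5, t0-10 and t0-15 min of each challenge so baselines exist.
    """
    disposal = disposal or DisposalParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = profile.times
    dt = float(t[1] - t[0]) if len(profile) > 1 else 1.0
    u = _rate_to_conc(profile.values, disposal.V_d)  # mmol/L/s
    if disposal.k_cl > 0:
        a = np.exp(-disposal.k_cl * dt)
        b = (1.0 - a) / disposal.k_cl
        dev = lfilter([0.0, b], [1.0, -a], u)
    else:
        dev = np.concatenate([[0.0], np.cumsum(u)[:-1] * dt])
    g = disposal.G_basal + dev
    if np.any(g <= 0):
        raise ValueError("disposal parameters produced non-positive glucose")
    dense = Series(t, g)

    sample_times = _arterial_schedule(t[0], t[-1], events or [], rng)
    idx = np.clip(np.round((sample_times - t[0]) / dt).astype(int), 0, len(t) - 1)
    sparse = Series(t[idx], g[idx])
    return dense, sparse


def _arterial_schedule(
    t0: float, t1: float, events: list[InfusionEvent], rng: np.random.Generator
) -> np.ndarray:
    times: list[float] = []
    for ev in events:
        # the four baseline samples, then dense 30 s coverage of the challenge
        times.extend(ev.t_start - np.array([900.0, 600.0, 300.0, 0.0]))
        times.extend(np.arange(ev.t_start + 30.0, ev.t_end + 900.0, 30.0))
    # background sampling at irregular 3-10 min intervals
    tcur = t0
    while tcur <= t1:
        times.append(tcur)
        tcur += rng.uniform(180.0, 600.0)
    arr = np.unique(np.round(np.asarray(times)))
    return arr[(arr >= t0) & (arr <= t1)]


def first_order_response(
    u: np.ndarray, K: float, tau: float, theta_steps: int, dt: float = 1.0,
    y0: float | None = None,
) -> np.ndarray:
    """Exact-discretization solution of the sensor compartment model.

    y[k+1] = a y[k] + (1-a) K u[k-theta], a = exp(-dt/tau). Before the
    record starts the input is held at u[0]; ``y0`` defaults to the
    stationary value K*u[0].
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    u = np.asarray(u, dtype=float)
    a = np.exp(-dt / tau)
    u_del = np.concatenate([np.full(theta_steps, u[0]), u[: len(u) - theta_steps]])
    base = K * u[0] if y0 is None else y0
    dev = lfilter([0.0, (1.0 - a)], [1.0, -a], K * u_del - base)
    return base + dev


def simulate_sensor(
    arterial_truth: Series,
    dyn: TrueDynamics,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
    meta: SensorMeta | None = None,
) -> tuple[SensorSeries, Series]:
    """Raw sensor stream plus its dense noiseless truth.

    The dense truth solves the compartment model against the arterial
    series; the transmitted value is the truth held on one-minute
    boundaries; reads occur at gaps uniform in [20, 22] s with additive
    glucose-dependent Gaussian noise, occasional offset outliers
    (|offset| uniform in [1, 3] mmol/L) and dropped samples.
    """
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = arterial_truth.times
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0):
        raise ValueError("arterial truth must be uniform at 1 s")
    theta_steps = int(round(dyn.theta))
    if theta_steps >= len(t):
        raise ValueError("theta exceeds the available lead-in")
    y = first_order_response(arterial_truth.values, dyn.K, dyn.tau, theta_steps)
    truth = Series(t, y)

    held = y[(np.arange(len(y)) // 60) * 60]  # one-minute zero-order hold
    read_times: list[float] = []
    tcur = float(t[0]) + rng.uniform(0.0, 20.0)
    while tcur <= t[-1]:
        read_times.append(tcur)
        tcur += rng.uniform(20.0, 22.0)
    rt = np.asarray(read_times)
    idx = np.floor(rt - t[0]).astype(int)
    vals = held[idx] + rng.normal(0.0, noise.sd(held[idx]))
    flags = np.full(rt.shape, "ok", dtype=object)

    is_out = rng.random(len(rt)) < noise.p_outlier
    mag = rng.uniform(1.0, 3.0, len(rt)) * rng.choice([-1.0, 1.0], len(rt))
    vals = np.where(is_out, vals + mag, vals)
    flags[is_out] = "outlier"

    keep = rng.random(len(rt)) >= noise.p_dropout
    flags[~keep] = "dropout"
    vals = np.clip(vals, 0.1, None)  # sensors never report non-positive glucose

    if meta is None:
        meta = SensorMeta(site=dyn.site, orientation=dyn.orientation,
                          fluid_regimen=dyn.fluid_regimen)
    raw = SensorSeries(rt[keep], vals[keep], meta=meta, flags=flags[keep])
    return raw, truth


def simulate_fluid_samples(
    sensed_truth: Series,
    interval: float = 300.0,
    noise_sd: float = 0.05,
    storage_drift: float | None = None,
    drift_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> Series:
    """Sparse peritoneal-fluid samples of the sensed glucose.

    When storage simulation is on (``storage_drift`` not None, default
    mean +0.1 mmol/L with SD 0.1) each sample additionally drifts as if
    stored on ice before analysis.
    """
    if interval < 60.0:
        raise ValueError("fluid sampling interval must be >= 60 s")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = sensed_truth.times
    st = np.arange(t[0], t[-1] + 1e-9, interval)
    idx = np.round(st - t[0]).astype(int)
    vals = sensed_truth.values[idx] + rng.normal(0.0, noise_sd, len(st))
    if storage_drift is not None:
        vals = vals + rng.normal(storage_drift, drift_sd, len(st))
    return Series(st, vals)


# ---------------------------------------------------------------------------
# whole-study generation

#: per-site true-dynamics population means; delays (s) and time constants (s)
#: follow the faster-IP / slower-SC pattern of peritoneal sensing studies
SITE_THETA_MEAN = {
    "IP_cranial_right": 175.0,
    "IP_cranial_left": 146.0,
    "IP_caudal_right": 156.0,
    "IP_caudal_left": 204.0,
    "SC_left": 241.0,
    "SC_right": 241.0,
}
SITE_TAU_MEAN = {
    "IP_cranial_right": 13.2 * 60,
    "IP_cranial_left": 8.6 * 60,
    "IP_caudal_right": 11.9 * 60,
    "IP_caudal_left": 15.6 * 60,
    "SC_left": 9.5 * 60,
    "SC_right": 9.5 * 60,
}


@dataclass
class StudyConfig:
    """Layout of one synthetic study (defaults mirror the study design)."""

    n_pigs: int = 12
    body_mass_kg: float = 45.0
    events: list[InfusionEvent] = field(default_factory=lambda: [
        InfusionEvent("clamp", 1800.0, 5400.0, 5.0),
        InfusionEvent("meal", 12000.0, 1800.0, 245.0),
        InfusionEvent("meal", 18000.0, 1800.0, 245.0),
    ])
    t_end: float = 23400.0
    disposal: DisposalParams = field(default_factory=DisposalParams)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    theta_pig_sd: float = 50.0    # s, between-pig delay offset
    theta_sensor_sd: float = 60.0  # s, residual per-sensor scatter
    tau_rel_sd: float = 0.3       # lognormal sigma on tau
    k_range: tuple[float, float] = (0.6, 1.4)  # uncalibrated gain spread
    fluid_interval: float = 300.0
    fluid_storage_drift: float | None = 0.1

    def __post_init__(self) -> None:
        validate_events(self.events)
        if self.n_pigs < 1:
            raise ValueError("need at least one pig")
        if self.t_end < max(e.t_end for e in self.events):
            raise ValueError("t_end must cover all events")


@dataclass
class SensorRecord:
    dyn: TrueDynamics
    raw: SensorSeries
    truth: Series


@dataclass
class Experiment:
    """One pig: infusions, arterial truth/samples, six sensors, fluid samples."""

    pig_id: str
    body_mass: float
    events: list[InfusionEvent]
    arterial_truth: Series
    arterial_samples: Series
    sensors: list[SensorRecord]
    fluid_samples: dict[str, Series]


@dataclass
class Study:
    config: StudyConfig
    seed: int
    experiments: list[Experiment]


def _draw_dynamics(site: str, orientation: str, regimen: str,
                   pig_theta_offset: float, cfg: StudyConfig,
                   rng: np.random.Generator) -> TrueDynamics:
    theta = rng.normal(SITE_THETA_MEAN[site] + pig_theta_offset, cfg.theta_sensor_sd)
    theta = float(np.clip(theta, 0.0, 880.0))
    tau = SITE_TAU_MEAN[site] * rng.lognormal(0.0, cfg.tau_rel_sd)
    tau = float(np.clip(tau, 60.0, 1800.0))
    K = float(rng.uniform(*cfg.k_range))
    return TrueDynamics(K=K, tau=tau, theta=theta, site=site,
                        orientation=orientation, fluid_regimen=regimen)


def simulate_experiment(
    config: StudyConfig | None = None,
    seed: int = 0,
    pig_index: int = 0,
    seed_seq: np.random.SeedSequence | None = None,
) -> Experiment:
    """One complete pig experiment, reproducible from (seed, pig_index)."""
    cfg = config or StudyConfig()
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence([seed, pig_index])
    s_art, s_pig, *s_sens = ss.spawn(2 + 6)
    rng_pig = np.random.default_rng(s_pig)

    regimen = "high" if pig_index % 2 == 0 else "low"
    pig_id = f"pig{pig_index + 1:02d}"
    profile = make_infusion_profile(cfg.events, 1.0, cfg.t_end, cfg.disposal)
    dense, sparse = simulate_arterial(profile, cfg.disposal,
                                      np.random.default_rng(s_art), cfg.events)

    pig_theta = rng_pig.normal(0.0, cfg.theta_pig_sd)
    sensors: list[SensorRecord] = []
    fluid: dict[str, Series] = {}
    for j, site in enumerate(IP_SITES + SC_SITES):
        rng_s = np.random.default_rng(s_sens[j])
        # element direction is set at insertion, effectively at random
        orient = (str(rng_s.choice(["toward_wall", "toward_viscera"]))
                  if is_ip(site) else "n/a")
        dyn = _draw_dynamics(site, orient, regimen, pig_theta, cfg, rng_s)
        meta = SensorMeta(pig_id=pig_id, site=site, orientation=orient,
                          fluid_regimen=regimen, sensor_id=f"{pig_id}_{site}")
        raw, truth = simulate_sensor(dense, dyn, cfg.noise, rng_s, meta)
        sensors.append(SensorRecord(dyn, raw, truth))
        if is_ip(site):
            fluid[site] = simulate_fluid_samples(
                truth, cfg.fluid_interval, 0.05, cfg.fluid_storage_drift, 0.1, rng_s
            )
    return Experiment(pig_id, cfg.body_mass_kg, list(cfg.events),
                      dense, sparse, sensors, fluid)


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> Study:
    """The full default study: 12 pigs x (4 IP + 2 SC) sensors."""
    cfg = config or StudyConfig()
    master = np.random.SeedSequence(seed)
    pig_seqs = master.spawn(cfg.n_pigs)
    exps = [
        simulate_experiment(cfg, seed, i, seed_seq=pig_seqs[i])
        for i in range(cfg.n_pigs)
    ]
    return Study(cfg, seed, exps)


def simulate_metrics_table(
    n_pigs: int = 12,
    challenges_per_sensor: int = 3,
    site_theta: dict[str, float] | None = None,
    pig_sd: float = 50.0,
    resid_sd: float = 100.0,
    seed: int | np.random.Generator = 0,
):
    """Direct cohort generator for statistical checks.

    Emits an included-records table with a known additive structure
    theta = site mean + pig intercept + noise, bypassing the signal
    pipeline, so mixed-model estimates can be compared with generator
    truth cheaply.
    """
    import pandas as pd

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    site_theta = site_theta or SITE_THETA_MEAN
    rows = []
    for i in range(n_pigs):
        pig = f"pig{i + 1:02d}"
        regimen = "high" if i % 2 == 0 else "low"
        b = rng.normal(0.0, pig_sd)
        for j, site in enumerate(IP_SITES + SC_SITES):
            orient = (str(rng.choice(["toward_wall", "toward_viscera"]))
                      if is_ip(site) else "n/a")
            for c in range(challenges_per_sensor):
                theta = site_theta[site] + b + rng.normal(0.0, resid_sd)
                rows.append(dict(
                    recording_id=f"{pig}_{site}_c{c}", pig_id=pig, site=site,
                    orientation=orient, fluid_regimen=regimen,
                    theta_s=theta, included=True,
                ))
    return pd.DataFrame(rows)
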