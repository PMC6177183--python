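"""Inclusion criteria, model-free dynamic metrics and cohort summaries.

A recording enters the statistical analysis only if the sensor was
stable before the challenge (|dG/dt| < 0.1 mmol/L/min throughout the
3 min window, strict) and the identified model fit exceeded 70%
(strict). Model-free timing metrics (time to 50% of maximum, time to
50% return to baseline) are computed on smoothed data from IV meals
only; clamps feed identification only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import interpolate_arterial
from .types import IdentifiedModel, Series, SmoothedSeries

STABILITY_RATE_LIMIT = 0.1  # mmol/L/min
FIT_THRESHOLD_PCT = 70.0
FLUID_DELAY_GRID_MAX = 600  # s; generous vs the expected 0-40 s band
FLUID_MIN_RISE = 0.5  # mmol/L; below this a fluid series is uninformative


def stability_check(smoothed: SmoothedSeries, t0: float) -> bool:
    """True iff the rate stays strictly below 0.1 mmol/L/min in absolute
    value at every grid point of the 3 min pre-challenge window."""
    m = (smoothed.times > t0 - 180.0) & (smoothed.times <= t0)
    rate = smoothed.rate[m]
    mean = smoothed.mean[m]
    if rate.size < 180 or np.any(~np.isfinite(mean)):
        raise WindowGapError("stability window missing or gapped")
    return bool(np.all(np.abs(rate) < STABILITY_RATE_LIMIT))


class WindowGapError(ValueError):
    """The pre-challenge window is not covered by smoothed data."""


def include_recording(
    model: IdentifiedModel | None, stable: bool,
    fit_threshold: float = FIT_THRESHOLD_PCT,
) -> tuple[bool, str]:
    """Apply the inclusion criteria in their stated order.

    Returns (included, reason); reason is the first failing criterion
    (stability before fit) or "none". Both criteria are strict
    inequalities: a rate of exactly 0.1 mmol/L/min is unstable and a fit
    of exactly 70% is excluded.
    """
    if not stable:
        return False, "unstable_baseline"
    if model is None or not (model.fit_pct > fit_threshold):
        return False, "low_fit"
    return True, "none"


def _crossing_time(times: np.ndarray, signal: np.ndarray, level: float,
                   rising: bool) -> float | None:
    """First time the signal crosses ``level`` (linear interpolation
    between bracketing 1 s grid points)."""
    above = signal >= level if rising else signal <= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(times[0])
    y0, y1 = signal[i - 1], signal[i]
    if y1 == y0:
        return float(times[i])
    frac = (level - y0) / (y1 - y0)
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def time_to_half_max(smoothed: SmoothedSeries, baseline: float,
                     window: tuple[float, float]) -> float:
    """Minutes from challenge start until the smoothed signal first
    reaches halfway between baseline and its window maximum."""
    t0, t_end = window
    m = (smoothed.times >= t0) & (smoothed.times <= t_end)
    t, g = smoothed.times[m], smoothed.mean[m]
    ok = np.isfinite(g)
    t, g = t[ok], g[ok]
    if t.size == 0:
        raise ValueError("empty challenge window")
    gmax = g.max()
    if gmax <= baseline:
        raise UndefinedMetricError("window maximum does not exceed baseline")
    level = baseline + 0.5 * (gmax - baseline)
    tc = _crossing_time(t, g, level, rising=True)
    return (tc - t0) / 60.0


def time_to_half_decline(smoothed: SmoothedSeries, baseline: float,
                         window: tuple[float, float]) -> float:
    """Minutes from challenge start until the signal first falls back to
    halfway between its peak and baseline (after the peak)."""
    t0, t_end = window
    m = (smoothed.times >= t0) & (smoothed.times <= t_end)
    t, g = smoothed.times[m], smoothed.mean[m]
    ok = np.isfinite(g)
    t, g = t[ok], g[ok]
    if t.size == 0:
        raise ValueError("empty challenge window")
    ipk = int(np.argmax(g))
    gmax = g[ipk]
    if gmax <= baseline:
        raise UndefinedMetricError("window maximum does not exceed baseline")
    level = baseline + 0.5 * (gmax - baseline)
    tc = _crossing_time(t[ipk:], g[ipk:], level, rising=False)
    if tc is None:
        raise UndefinedMetricError("signal never declines to half within the window")
    return (tc - t0) / 60.0


class UndefinedMetricError(ValueError):
    """The metric is undefined on this window (flagged, not a crash)."""


class UninformativeFluidError(ValueError):
    """Fluid series shows no usable rise over the challenge."""


def estimate_sensor_fluid_delay(
    sensor: SmoothedSeries,
    fluid: Series,
    grid_max: int = FLUID_DELAY_GRID_MAX,
    min_rise: float = FLUID_MIN_RISE,
) -> int:
    """Delay (s) of the sensor signal behind its local fluid samples.

    The sparse fluid samples are brought to the 1 s grid by the monotone
    cubic interpolant; for each candidate delay d in [0, grid_max] the
    one-step ARX(1,1) model y[k] = a y[k-1] + b u[k-d] + e[k] is solved
    by least squares and the delay with the smallest prediction-error
    sum of squares wins (ties: smallest d). The input gain is
    constrained to b >= 0 (sensor and fluid track the same glucose, so
    the steady-state gain is positive); a delay whose unconstrained gain
    turns negative falls back to the AR-only fit and cannot win on a
    spurious trend correction.
    """
    if len(fluid) < 6:
        raise ValueError("need at least 6 fluid samples spanning the challenge")
    if np.ptp(fluid.values) < min_rise:
        raise UninformativeFluidError(
            f"fluid rise {np.ptp(fluid.values):.2f} mmol/L < {min_rise} mmol/L"
        )
    u_dense = interpolate_arterial(fluid)  # same monotone interpolant
    t_lo = max(sensor.times[0], u_dense.times[0])
    t_hi = min(sensor.times[-1], u_dense.times[-1])
    ys = sensor.mean[(sensor.times >= t_lo) & (sensor.times <= t_hi)]
    us = u_dense.values[(u_dense.times >= t_lo) & (u_dense.times <= t_hi)]
    n = len(ys)
    if n <= grid_max + 2:
        raise ValueError("overlap too short for the delay grid")
    best = None
    for d in range(grid_max + 1):
        yk = ys[d + 1:]
        X = np.column_stack([ys[d:-1], us[1: n - d]])
        ok = np.all(np.isfinite(X), axis=1) & np.isfinite(yk)
        coef, _, _, _ = np.linalg.lstsq(X[ok], yk[ok], rcond=None)
        if coef[1] < 0:
            a = np.linalg.lstsq(X[ok, :1], yk[ok], rcond=None)[0]
            coef = np.array([a[0], 0.0])
        r = yk[ok] - X[ok] @ coef
        sse = float(r @ r) / ok.sum()
        if best is None or sse < best[0] - 1e-15:
            best = (sse, d)
    return best[1]


@dataclass
class NormalizedCohort:
    times: np.ndarray          # challenge-relative seconds
    mean: np.ndarray           # cohort mean scaled to [0, 1]
    series: np.ndarray         # (n_series, n_t) individually scaled curves
    sd: np.ndarray             # pointwise SD of the scaled curves


def normalize_cohort(series_list: list[np.ndarray],
                     times: np.ndarray | None = None) -> NormalizedCohort:
    """Cohort normalization of baseline-subtracted, challenge-aligned curves.

    The pointwise mean across curves is scaled to the range [0, 1]; the
    identical affine scale is then applied to every individual curve
    before the SD band is computed.
    """
    if len(series_list) == 0:
        raise ValueError("empty series list")
    arr = np.vstack([np.asarray(s, dtype=float) for s in series_list])
    if times is None:
        times = np.arange(arr.shape[1], dtype=float)
    m = np.nanmean(arr, axis=0)
    lo, hi = np.nanmin(m), np.nanmax(m)
    if hi == lo:
        raise ValueError("cohort mean is constant; cannot scale to [0, 1]")
    scale = 1.0 / (hi - lo)
    mean_scaled = (m - lo) * scale
    series_scaled = (arr - lo) * scale
    sd = np.nanstd(series_scaled, axis=0, ddof=1) if arr.shape[0] > 1 else \
        np.zeros(arr.shape[1])
    return NormalizedCohort(np.asarray(times, dtype=float), mean_scaled,
                            series_scaled, sd)


def diffusion_time(distance_cm: float, D_cm2_s: float) -> float:
    """One-dimensional diffusion time t = x^2 / (2 D).

    With D = 6.7e-6 cm^2/s (glucose in water at 25 C) a 1 mm path takes
    about 750 s — the physical floor under fluid-phase peritoneal sensing.
    """
    if distance_cm < 0:
        raise ValueError("distance must be >= 0")
    if D_cm2_s <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    return distance_cm**2 / (2.0 * D_cm2_s)
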