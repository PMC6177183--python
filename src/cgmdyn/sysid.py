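"""First-order-plus-dead-time identification per glucose challenge.

The dynamics between arterial glucose G_IA and sensed glucose G_sens are

    dG_sens/dt = (K * G_IA(t - theta) - G_sens) / tau

Identification is output-error least squares in the time domain on
baseline-subtracted 1 s series: delays 0..900 s are scanned at 1 s
resolution; for each fixed delay the time constant is found by a bounded
scalar search (on log tau) with the gain obtained in closed form, and the
delay with the smallest output MSE wins (ties: smallest delay). For a
first-order single-input model with fixed delay this reaches the same
optimum as the frequency-domain transfer-function fit it replaces.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter

from .types import BaselinePair, IdentifiedModel, Series, SmoothedSeries

THETA_GRID = np.arange(0, 901)
TAU_BOUNDS = (10.0, 7200.0)


def arterial_baseline(samples: Series, t0: float, slot_tol: float = 90.0) -> float:
    """Stationary arterial value: mean of the sample at challenge start
    and the three preceding samples at roughly 5-minute spacing.

    Each slot (t0, t0-5, t0-10, t0-15 min) is matched to the nearest
    sample within ``slot_tol`` seconds.
    """
    slots = t0 - np.array([900.0, 600.0, 300.0, 0.0])
    vals, missing = [], []
    for s in slots:
        i = int(np.argmin(np.abs(samples.times - s)))
        if abs(samples.times[i] - s) <= slot_tol:
            vals.append(samples.values[i])
        else:
            missing.append(f"t0{(s - t0) / 60:+.0f} min")
    if missing:
        raise ValueError(
            "arterial baseline needs samples at t0, -5, -10 and -15 min; "
            f"missing slots: {', '.join(missing)}"
        )
    return float(np.mean(vals))


def sensor_baseline(smoothed: SmoothedSeries, t0: float,
                    max_gap_frac: float = 0.1) -> float:
    """Mean smoothed sensor value over the last 3 min before the challenge."""
    m = (smoothed.times > t0 - 180.0) & (smoothed.times <= t0)
    vals = smoothed.mean[m]
    if vals.size < 180:
        raise ValueError("smoothed series does not cover the 3 min baseline window")
    frac_missing = np.mean(~np.isfinite(vals))
    if frac_missing > max_gap_frac:
        raise ValueError(
            f"baseline window has {frac_missing:.0%} gaps (> {max_gap_frac:.0%})"
        )
    return float(np.nanmean(vals))


def simulate_first_order(u: np.ndarray, K: float, tau: float, theta: int) -> np.ndarray:
    """Exact-discretization response from zero initial state.

    y[k+1] = a y[k] + (1-a) K u[k-theta], a = exp(-1/tau); the input is
    zero before the record starts (baseline-subtracted data).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    u = np.asarray(u, dtype=float)
    a = np.exp(-1.0 / tau)
    u_del = np.concatenate([np.zeros(int(theta)), u[: len(u) - int(theta)]])
    return lfilter([0.0, 1.0 - a], [1.0, -a], K * u_del)


def goodness_of_fit(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalized-RMSE fit percentage: 100 * (1 - ||y - yhat|| / ||y - mean(y)||).

    100 is a perfect fit, 0 no better than the mean; negative is worse
    than the mean.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("y has zero variance; fit percentage undefined")
    return float(100.0 * (1.0 - np.linalg.norm(y - yhat) / denom))


def _best_tau_k(u_del: np.ndarray, y: np.ndarray, mask: np.ndarray,
                tau_bounds: tuple[float, float]) -> tuple[float, float, float]:
    """Inner solve at fixed delay: scalar search over tau on a log scale,
    closed-form least-squares gain. Returns (tau, K, sse)."""

    def sse_of(log_tau: float) -> tuple[float, float]:
        a = np.exp(-np.exp(-log_tau))  # a = exp(-1/tau)
        s = lfilter([0.0, 1.0 - a], [1.0, -a], u_del)[mask]
        ss = s @ s
        K = (s @ y) / ss if ss > 0 else 0.0
        r = y - K * s
        return r @ r, K

    lo, hi = np.log(tau_bounds[0]), np.log(tau_bounds[1])
    res = minimize_scalar(lambda lt: sse_of(lt)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-8})
    sse, K = sse_of(res.x)
    return float(np.exp(res.x)), float(K), float(sse)


def fit_delay_model(
    u: np.ndarray,
    y: np.ndarray,
    baselines: BaselinePair,
    theta_grid: np.ndarray = THETA_GRID,
    tau_bounds: tuple[float, float] = TAU_BOUNDS,
    max_gap_frac: float = 0.1,
) -> IdentifiedModel:
    """Exhaustive delay scan with output-error least squares per delay.

    ``u`` and ``y`` are baseline-subtracted series aligned on the same
    1 s grid over the challenge window. NaN samples in ``y`` (gaps left
    by the smoother) are excluded pairwise, provided they are under
    ``max_gap_frac`` of the window.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if u.shape != y.shape:
        raise ValueError("u and y must be aligned on the same grid")
    if len(y) < 600:
        raise ValueError("challenge window shorter than 600 s")
    mask = np.isfinite(y)
    if np.mean(~mask) > max_gap_frac:
        raise ValueError("more than 10% of the window is missing after smoothing")
    ym = y[mask]
    if np.ptp(ym) == 0:
        raise ValueError("sensor series is degenerate (zero variance)")

    best = None
    for theta in np.asarray(theta_grid, dtype=int):
        u_del = np.concatenate([np.zeros(theta), u[: len(u) - theta]])
        tau, K, sse = _best_tau_k(u_del, ym, mask, tau_bounds)
        if best is None or sse < best[0] - 1e-12:  # strict: ties keep smaller theta
            best = (sse, int(theta), tau, K)
    sse, theta, tau, K = best
    yhat = simulate_first_order(u, K, tau, theta)[mask]
    return IdentifiedModel(
        K=K, tau=tau, theta=float(theta),
        fit_pct=goodness_of_fit(ym, yhat),
        mse=float(sse / ym.size),
        window=(0.0, float(len(y) - 1)),
        baseline=baselines,
    )


def mse_at_theta(u: np.ndarray, y: np.ndarray, theta: int,
                 tau_bounds: tuple[float, float] = TAU_BOUNDS) -> float:
    """Output MSE of the best (K, tau) at one fixed delay (diagnostics)."""
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    u_del = np.concatenate([np.zeros(int(theta)), u[: len(u) - int(theta)]])
    _, _, sse = _best_tau_k(u_del, y[mask], mask, tau_bounds)
    return float(sse / mask.sum())
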