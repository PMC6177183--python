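"""Domain containers shared across the pipeline.

All timestamps are seconds from the experiment origin and all glucose
values are mmol/L. Sensor streams are irregular (~20-22 s cadence);
smoothed series live on a uniform 1 s grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

IP_SITES = (
    "IP_cranial_right",
    "IP_cranial_left",
    "IP_caudal_right",
    "IP_caudal_left",
)
SC_SITES = ("SC_left", "SC_right")
SITES = IP_SITES + SC_SITES

ORIENTATIONS = ("toward_wall", "toward_viscera", "n/a")
FLUID_REGIMENS = ("high", "low")
EVENT_KINDS = ("meal", "clamp", "bolus")

#: standard IV-meal dose (mg glucose / kg body weight) and duration (s)
MEAL_DOSE_MG_PER_KG = 245.0
MEAL_DURATION_S = 1800.0


def is_ip(site: str) -> bool:
    return site.startswith("IP_")


@dataclass(frozen=True)
class InfusionEvent:
    """One glucose challenge.

    ``dose`` is mg glucose per kg body weight for meals/boluses, or the
    target plateau rise in mmol/L for clamps.
    """

    kind: str
    t_start: float
    duration: float
    dose: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("meal", "clamp") and not self.duration > 0:
            raise ValueError(f"{self.kind} duration must be > 0, got {self.duration}")
        if self.kind == "clamp" and not (4800.0 <= self.duration <= 6600.0):
            raise ValueError(
                f"clamp duration must lie in [4800, 6600] s, got {self.duration}"
            )
        if self.dose <= 0:
            raise ValueError("dose must be > 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


def validate_events(events: list[InfusionEvent]) -> None:
    """Reject unordered or overlapping challenges."""
    for prev, nxt in zip(events, events[1:]):
        if nxt.t_start < prev.t_end:
            raise ValueError(
                f"events overlap or are unordered: {prev.kind} ending at "
                f"{prev.t_end:.0f} s vs {nxt.kind} starting at {nxt.t_start:.0f} s"
            )


@dataclass(frozen=True)
class TrueDynamics:
    """Ground-truth first-order-plus-delay sensor dynamics.

    K is the dimensionless steady-state gain, tau the time constant (s)
    and theta the pure dead time (s) between arterial change and the
    earliest sensed response.
    """

    K: float
    tau: float
    theta: float
    site: str
    orientation: str = "n/a"
    fluid_regimen: str = "high"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.fluid_regimen not in FLUID_REGIMENS:
            raise ValueError(f"unknown fluid regimen {self.fluid_regimen!r}")
        if is_ip(self.site) != (self.orientation != "n/a"):
            raise ValueError("orientation must be n/a iff site is subcutaneous")


@dataclass(frozen=True)
class NoiseConfig:
    """Glucose-dependent measurement noise (worst-case ISO 15197:2013).

    Absolute SD ``sd_low`` applies for G <= 5.55 mmol/L, relative SD
    ``rel_high``·G above.
    """

    sd_low: float = 0.83 / 2
    rel_high: float = 0.15 / 2
    p_outlier: float = 0.01
    p_dropout: float = 0.01

    def __post_init__(self) -> None:
        if self.sd_low < 0 or self.rel_high < 0:
            raise ValueError("noise SDs must be >= 0")
        for p in (self.p_outlier, self.p_dropout):
            if not (0 <= p < 1):
                raise ValueError("probabilities must lie in [0, 1)")

    def sd(self, g: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        return np.where(g <= 5.55, self.sd_low, self.rel_high * g)


@dataclass
class Series:
    """A timestamped glucose series (dense or sparse)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def window(self, t_lo: float, t_hi: float) -> "Series":
        m = (self.times >= t_lo) & (self.times <= t_hi)
        return Series(self.times[m], self.values[m])


@dataclass
class SensorMeta:
    pig_id: str = ""
    site: str = "SC_left"
    orientation: str = "n/a"
    fluid_regimen: str = "high"
    sensor_id: str = ""


@dataclass
class SensorSeries:
    """Raw irregular sensor stream with placement metadata.

    ``flags`` is synthetic-truth bookkeeping (ok|outlier|dropout); the
    analysis path never reads it.
    """

    times: np.ndarray
    values: np.ndarray
    meta: SensorMeta = field(default_factory=SensorMeta)
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sensor times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensor values must be finite")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=object)

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray) -> "SensorSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class SmoothedSeries:
    """Uniform 1 s series with posterior SD and rate estimate.

    ``mean`` may contain NaN where the outlier pass left gaps with no
    usable measurement support; ``rate`` is mmol/L/min.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    rate: np.ndarray
    removed_count: int = 0
    meta: SensorMeta = field(default_factory=SensorMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("mean", "sd", "rate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.times.size > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0):
                raise ValueError("smoothed series must live on a uniform 1 s grid")
        if np.any(self.sd < 0):
            raise ValueError("posterior sd must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def window(self, t_lo: float, t_hi: float) -> "SmoothedSeries":
        m = (self.times >= t_lo) & (self.times <= t_hi)
        return SmoothedSeries(
            self.times[m], self.mean[m], self.sd[m], self.rate[m],
            removed_count=self.removed_count, meta=self.meta,
        )


@dataclass
class BaselinePair:
    """Stationary (pre-challenge) levels subtracted before identification."""

    g_ia_stat: float
    g_sens_stat: float
    t0: float

    def __post_init__(self) -> None:
        for v in (self.g_ia_stat, self.g_sens_stat):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("baseline values must be finite and > 0")


@dataclass
class IdentifiedModel:
    """First-order-plus-dead-time fit for one recording x one challenge."""

    K: float
    tau: float
    theta: float
    fit_pct: float
    mse: float
    window: tuple[float, float]
    baseline: BaselinePair

    def __post_init__(self) -> None:
        if not (0 <= self.theta <= 900):
            raise ValueError("theta must lie in [0, 900] s")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.fit_pct > 100 + 1e-9:
            raise ValueError("fit_pct cannot exceed 100")
        if self.mse < 0:
            raise ValueError("mse must be >= 0")


EXCLUSION_REASONS = ("unstable_baseline", "low_fit", "window_gap", "none")


@dataclass
class MetricsRecord:
    """Inclusion decision plus dynamic parameters for one recording."""

    recording_id: str
    included: bool
    exclusion_reason: str
    theta_s: Optional[float] = None
    tau_s: Optional[float] = None
    fit_pct: Optional[float] = None
    t50max_min: Optional[float] = None
    t50decline_min: Optional[float] = None
    site: str = ""
    orientation: str = "n/a"
    fluid_regimen: str = "high"
    pig_id: str = ""
    challenge_kind: str = ""

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.included and self.exclusion_reason != "none":
            raise ValueError("included records carry reason 'none'")
        if not self.included:
            # excluded records carry no metric values
            self.theta_s = self.tau_s = None
            self.t50max_min = self.t50decline_min = None
        if (
            self.t50max_min is not None
            and self.t50decline_min is not None
            and self.t50max_min > self.t50decline_min
        ):
            raise ValueError("t50max must not exceed t50decline")
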