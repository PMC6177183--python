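"""Shared fixtures: small synthetic experiments reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from cgmdyn import preprocess, synth, types


@pytest.fixture(scope="session")
def meal_events() -> list[types.InfusionEvent]:
    return [types.InfusionEvent("meal", 1200.0, 1800.0, 245.0)]


@pytest.fixture(scope="session")
def meal_arterial(meal_events):
    """Dense + sparse arterial response to one standard IV meal."""
    profile = synth.make_infusion_profile(meal_events, 1.0, 6600.0)
    dense, sparse = synth.simulate_arterial(profile, seed=11, events=meal_events)
    return dense, sparse


@pytest.fixture(scope="session")
def ip_dynamics() -> types.TrueDynamics:
    """Typical intraperitoneal sensor dynamics (delay ~3 min, tau ~12 min)."""
    return types.TrueDynamics(K=1.0, tau=732.0, theta=170.0,
                              site="IP_cranial_left", orientation="toward_wall")


@pytest.fixture(scope="session")
def noisy_sensor(meal_arterial, ip_dynamics):
    """One noisy sensor recording of the standard meal plus its dense truth."""
    dense, _ = meal_arterial
    raw, truth = synth.simulate_sensor(dense, ip_dynamics,
                                       types.NoiseConfig(), seed=21)
    return raw, truth


@pytest.fixture(scope="session")
def smoothed_sensor(noisy_sensor):
    raw, _ = noisy_sensor
    return preprocess.kalman_smooth(preprocess.median_filter(raw, 5))


@pytest.fixture(scope="session")
def tiny_study():
    """Two pigs, two IV meals each - the smallest full-pipeline study."""
    cfg = synth.StudyConfig(
        n_pigs=2,
        events=[types.InfusionEvent("meal", 1500.0, 1800.0, 245.0),
                types.InfusionEvent("meal", 7500.0, 1800.0, 245.0)],
        t_end=12600.0,
    )
    return synth.simulate_study(cfg, seed=77)
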