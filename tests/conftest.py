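"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from forcespec.curves import convert_to_force_separation
from forcespec.pipeline import analyze_map
from forcespec.simulate import PullingConfig, scenario_presets, simulate_pull


@pytest.fixture(scope="session")
def noise_free_config() -> PullingConfig:
    return PullingConfig(force_noise_sigma_pN=0.0, seed=11)


@pytest.fixture(scope="session")
def default_config() -> PullingConfig:
    return PullingConfig(seed=11)


@pytest.fixture(scope="session")
def wildtype_curves(default_config):
    """120 specific wild-type pulls with their ground-truth event logs."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(120):
        out.append(
            simulate_pull(
                default_config, scenario_presets("wild-type"), f"wt-{i:03d}", rng=rng
            )
        )
    return out


@pytest.fixture(scope="session")
def wildtype_analysis(wildtype_curves):
    return analyze_map([c for c, _ in wildtype_curves])


@pytest.fixture()
def noise_free_double(noise_free_config):
    """One noise-free wild-type double-rupture pull (truth has two events)."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        curve, events = simulate_pull(
            noise_free_config, scenario_presets("wild-type"), "nf", rng=rng
        )
        if len(events) == 2 and events[0].force_pN > 40:
            return curve, events
    raise RuntimeError("no double-rupture draw found")  # pragma: no cover


@pytest.fixture()
def processed_noise_free_double(noise_free_double):
    curve, events = noise_free_double
    return convert_to_force_separation(curve), events
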