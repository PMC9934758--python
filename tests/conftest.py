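"""Shared fixtures: configurations and cached long simulations.

The expensive 300-day simulations are session-scoped and shared between the
behavioral tests and the acceptance suite so the whole run stays fast.
"""

import warnings

import pytest

from arterygr import ModelConfig, build_scenario, simulate


@pytest.fixture(scope="session")
def config():
    """Calibrated defaults (warnings from the tone-balance absorption muted)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ModelConfig()


@pytest.fixture(scope="session")
def config_ks2(config):
    return config.replace(K_sigma_c=2.0, K_sigma_m=2.0)


@pytest.fixture(scope="session")
def config_ks3(config):
    return config.replace(K_sigma_c=3.0, K_sigma_m=3.0)


def _run(scenario, cfg, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate(scenario, cfg, **kw)


@pytest.fixture(scope="session")
def homeostatic_run(config):
    """300 days with no perturbation: the discrete fixed point."""
    return _run(build_scenario("step_flow", 1.0), config, duration=300.0)


@pytest.fixture(scope="session")
def flow_decrease_run(config_ks2):
    """30% sustained flow decrease, 300 days."""
    return _run(build_scenario("step_flow", 0.7), config_ks2, duration=300.0)


@pytest.fixture(scope="session")
def flow_increase_run(config_ks2):
    """30% sustained flow increase, 300 days."""
    return _run(build_scenario("step_flow", 1.3), config_ks2, duration=300.0)


@pytest.fixture(scope="session")
def pressure_run(config_ks2):
    """50% sustained pressure increase, 300 days."""
    return _run(build_scenario("step_pressure", 1.5), config_ks2, duration=300.0)


@pytest.fixture(scope="session")
def pressure_run_ks3(config_ks3):
    """50% pressure increase with the stress gains of the tone diagnostics."""
    return _run(build_scenario("step_pressure", 1.5), config_ks3, duration=300.0)


@pytest.fixture(scope="session")
def flow_decrease_run_ks3(config_ks3):
    return _run(build_scenario("step_flow", 0.7), config_ks3, duration=300.0)


def run_quiet(scenario, cfg, **kw):
    """Module-level helper for tests that need bespoke short runs."""
    return _run(scenario, cfg, **kw)
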