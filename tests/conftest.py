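import numpy as np
import pandas as pd
import pytest

from canopylux.simulate import (
    LightSimConfig,
    NoiseConfig,
    SensorConfig,
    SimConfig,
    simulate_deployment,
)


def noise_free_config(**kwargs) -> SimConfig:
    """Idealized deployment: no cloud, no sensor noise, no floor/quantization."""
    defaults = dict(
        n_days=10,
        light=LightSimConfig(cloud_sigma=0.0),
        noise=NoiseConfig(sigma_open=0.0, sigma_canopy=0.0),
        sensor=SensorConfig(floor_lux=0.0, quantization_lux=0.0),
        seed=0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_noise_free_deployment():
    return simulate_deployment(noise_free_config())


def run_recovery_pipeline(seed: int, **config_kwargs):
    """Simulate a deployment and run it through index + trend; returns the summary."""
    from canopylux.pipeline import compute_index_table, trend_summary

    config = SimConfig(seed=seed, **config_kwargs)
    deployment = simulate_deployment(config)
    table, counts = compute_index_table(deployment.to_series(), site=config.site)
    _, summary = trend_summary(table, span=0.4, k_a=config.canopy.k_a)
    return deployment, table, counts, summary
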