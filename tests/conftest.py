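import numpy as np
import pytest

from suturelax import (
    SensorConfig,
    builtin_profiles,
    sample_suture_params,
    synthesize_trace,
)


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def noiseless_sensor():
    return SensorConfig(noise_sd_n=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(profiles, noiseless_sensor):
    """Factory for noiseless, SD-zeroed traces, cached per (tissue, mode)."""
    cache = {}

    def factory(tissue: str, mode: str):
        key = (tissue, mode)
        if key not in cache:
            profile = profiles[tissue].with_zero_sds()
            rng = np.random.default_rng(0)
            params = sample_suture_params(profile, mode=mode, rng=rng)
            cache[key] = (
                synthesize_trace(params, noiseless_sensor, rng,
                                 suture_id=f"{tissue}_{mode}"),
                params,
            )
        return cache[key]

    return factory
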