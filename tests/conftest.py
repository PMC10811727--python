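from dataclasses import replace

import pytest

from alkanox.simulate import NoiseSD, scenario_library, simulate


@pytest.fixture(scope="session")
def presets():
    return scenario_library()


@pytest.fixture(scope="session")
def ethane_noise_free(presets):
    """Noise-free ethane-like run: (series, isotopes=None, ground truth)."""
    params = replace(presets["ethane-like"], noise_sd=NoiseSD())
    return simulate(params)


@pytest.fixture(scope="session")
def butane_noise_free(presets):
    params = replace(presets["butane-like"], noise_sd=NoiseSD())
    return simulate(params)
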