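import numpy as np
import pytest

from duplexkit import synth
from duplexkit.thermo import StrandConcentration, ThermoParams


@pytest.fixture
def nful_params() -> ThermoParams:
    """Lesion-with-linker duplex: dH −119.4 kcal/mol, dS −339 cal/(mol·K)."""
    return ThermoParams.from_kcal(-119.4, -339.0)


@pytest.fixture
def nfus_params() -> ThermoParams:
    """Linkerless-lesion duplex: dH −103.5 kcal/mol, dS −295 cal/(mol·K)."""
    return ThermoParams.from_kcal(-103.5, -295.0)


@pytest.fixture
def ct20() -> StrandConcentration:
    return StrandConcentration.from_micromolar(20.0)


@pytest.fixture
def noiseless_cfg() -> synth.GeneratorConfig:
    return synth.GeneratorConfig(
        seed=0,
        scenario="nFluL",
        melting_sigma=0.0,
        spectrum_sigma_frac=0.0,
        band_sigma_frac=0.0,
        tm_sigma=0.0,
    )


def make_noiseless(scenario: str, seed: int = 0, **overrides) -> synth.GeneratorConfig:
    kwargs = dict(
        seed=seed,
        scenario=scenario,
        melting_sigma=0.0,
        spectrum_sigma_frac=0.0,
        band_sigma_frac=0.0,
        tm_sigma=0.0,
    )
    kwargs.update(overrides)
    return synth.GeneratorConfig(**kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
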