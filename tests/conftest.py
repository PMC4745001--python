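import numpy as np
import pytest

from flexselect import EffectVector, NuisanceParams, TrialDesign


@pytest.fixture
def base_design() -> TrialDesign:
    """The motivating trial's base design: 3 arms, 40/100 interim, 200 final."""
    return TrialDesign(k=3, n1=40, N1=100, n2=200, alpha=0.025)


@pytest.fixture
def null_effects() -> EffectVector:
    return EffectVector.null(3)


def nuis(rho: float, sigma: float = 1.0, sigma0: float = 1.0) -> NuisanceParams:
    return NuisanceParams(sigma=sigma, sigma0=sigma0, rho=rho)
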