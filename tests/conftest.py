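import numpy as np
import pytest

from tobitkit import (
    CensoringBounds,
    CensoredVariable,
    ModRegCondition,
    PairedCondition,
    PairedSample,
    gen_modreg,
    gen_paired,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def censored_paired_sample():
    """Moderately censored paired data at a known condition."""
    return gen_paired(
        PairedCondition(d=0.5, sdr=1.5, rho=0.5, cp=0.2, n=200, seed=42)
    )


@pytest.fixture
def uncensored_paired_sample():
    return gen_paired(
        PairedCondition(d=0.5, sdr=1.5, rho=0.5, cp=0.0, n=200, seed=43)
    )


@pytest.fixture
def scenario1_data():
    """x and y ceiling-censored at a shared threshold, z observed."""
    return gen_modreg(
        ModRegCondition(
            scenario="xy_censored", beta3=0.39, rho=0.3, cp=0.2, n=200, seed=44
        )
    )


@pytest.fixture
def uncensored_modreg_data():
    return gen_modreg(
        ModRegCondition(beta3=0.39, rho=0.3, cp=0.0, n=200, seed=45)
    )


def make_variable(values, floor=-np.inf, ceiling=np.inf):
    return CensoredVariable.from_observed(
        np.asarray(values, float), CensoringBounds(floor, ceiling)
    )


def make_paired(y1, y2, floor=-np.inf, ceiling=np.inf):
    return PairedSample(
        pre=make_variable(y1, floor, ceiling),
        post=make_variable(y2, floor, ceiling),
    )
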