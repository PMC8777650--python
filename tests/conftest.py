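import numpy as np
import pytest

from pelletpk import datasets
from pelletpk.pk import PKParams


@pytest.fixture(scope="session")
def sobrerol_params() -> PKParams:
    """The reconstructed sobrerol two-compartment parameter set."""
    return datasets.SOBREROL_PK_PARAMS


@pytest.fixture(scope="session")
def profile_300mg():
    """The eight-point single-dose 300 mg plasma profile."""
    return datasets.SOBREROL_300MG_PROFILE


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_feasible_params(rng: np.random.Generator, with_lag: bool = True) -> PKParams:
    """A random, non-degenerate PK parameter set for property checks."""
    while True:
        k12, k21, k10, ka = np.exp(rng.uniform(np.log(0.05), np.log(5.0), size=4))
        p = PKParams(
            k12=k12,
            k21=k21,
            k10=k10,
            ka=ka,
            tlag=rng.uniform(0.0, 0.2) if with_lag else 0.0,
            Vd=rng.uniform(5_000.0, 80_000.0),
        )
        if min(abs(p.ka - p.alpha), abs(p.ka - p.beta)) > 1e-3:
            return p
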