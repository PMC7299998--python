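import numpy as np
import pytest

from aggkinetics.kinetic_model import RateConstants
from aggkinetics.synthetic_data import (
    DEFAULT_RATIOS,
    InhibitorModel,
    TurbidityModel,
    generate_tht_plate,
    generate_turbidity_plate,
)

# combined rate constants used as generator ground truth throughout the suite
UNINHIBITED = (6.4, 2.74e5)
INHIBITED = (10.8, 0.4e5)

M0_SERIES = tuple(u * 1e-6 for u in (1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 9.0))

RESIDUAL_MAP = {0.0: 1.0, 0.1: 0.75, 0.3: 0.45, 0.5: 0.25, 0.7: 0.12, 1.0: 0.05}


@pytest.fixture(scope="session")
def uninhibited_rc() -> RateConstants:
    return RateConstants.from_combined(*UNINHIBITED)


@pytest.fixture(scope="session")
def inhibited_rc() -> RateConstants:
    return RateConstants.from_combined(*INHIBITED)


@pytest.fixture(scope="session")
def k2_inhibitor() -> InhibitorModel:
    return InhibitorModel(
        target="k2",
        dose_factor_map={d: 1.0 / (1.0 + 3.0 * d) for d in DEFAULT_RATIOS},
    )


@pytest.fixture(scope="session")
def tht_concentration_plate(uninhibited_rc):
    """Small multi-concentration ThT plate (4 loads x 2 reps, for speed)."""
    return generate_tht_plate(
        uninhibited_rc,
        m0_list=[1.5e-6, 3e-6, 5e-6, 9e-6],
        noise_sd=0.02,
        n_reps=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tht_dose_plate(uninhibited_rc, k2_inhibitor):
    return generate_tht_plate(
        uninhibited_rc,
        m0_list=[3e-6],
        inhib=k2_inhibitor,
        doses=DEFAULT_RATIOS,
        noise_sd=0.02,
        n_reps=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def turbidity_model() -> TurbidityModel:
    return TurbidityModel(
        plateau=1.0, rate=2e-3, onset=1800.0, residual_fraction_map=dict(RESIDUAL_MAP)
    )


@pytest.fixture(scope="session")
def turbidity_plate(turbidity_model):
    return generate_turbidity_plate(
        turbidity_model, noise_sd=0.01, seed=5, block_gain=0.1
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
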