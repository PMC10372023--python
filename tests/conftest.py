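import numpy as np
import pytest

from ftgr import (
    GrowthSimParams,
    SystemConstants,
    TreatmentEffect,
    VolumeSeries,
)


@pytest.fixture
def worked_series() -> VolumeSeries:
    """The hand-checked 4-point series V = (60, 80, 90, 120) on a 2-day grid."""
    return VolumeSeries("worked", [0, 2, 4, 6], [60.0, 80.0, 90.0, 120.0],
                        [6, 6, 6, 6])


@pytest.fixture
def noiseless_params() -> GrowthSimParams:
    return GrowthSimParams(noise_cv=0.0)


@pytest.fixture
def default_effect() -> TreatmentEffect:
    return TreatmentEffect()


@pytest.fixture
def thermal_constants() -> SystemConstants:
    """Constants mirroring the characterization setup: 0.65 W over 1 cm**2,
    1 g of water, plateau ~43 C from 25 C ambient at eta ~0.73."""
    return SystemConstants(
        sample_mass=1.0,
        specific_heat=4.186,
        laser_power=0.65,
        absorbance_808=0.5,
        ambient_temp=25.0,
        heat_transfer=0.0181,
    )


def exp_series(v0: float, rate: float, days: np.ndarray) -> VolumeSeries:
    """Exact exponential volume series — FTGR must vanish on it."""
    days = np.asarray(days, dtype=int)
    return VolumeSeries("exp", days, v0 * np.exp(rate * days),
                        np.ones(len(days), dtype=int))
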