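import numpy as np
import pytest

from methylrelax import ArrheniusParams, FieldConditions, MethylGeometry


@pytest.fixture(scope="session")
def field800() -> FieldConditions:
    """800 MHz 1H spectrometer spinning at 19.2 kHz."""
    return FieldConditions.from_proton_mhz(800.0, 19.2)


@pytest.fixture(scope="session")
def geom() -> MethylGeometry:
    """Standard methyl geometry without librational scaling."""
    return MethylGeometry(theta_is_deg=69.1, r_is=1.106, s2=1.0)


@pytest.fixture(scope="session")
def geom93(geom) -> MethylGeometry:
    """Methyl geometry with the librational order parameter S^2 = 0.93."""
    return geom.with_s2(0.93)


@pytest.fixture(scope="session")
def arrhenius_full() -> ArrheniusParams:
    """Arrhenius parameters of the spin-diffusion (bath) analysis."""
    return ArrheniusParams(ea=3.5, tau0=2.5e-13)


@pytest.fixture(scope="session")
def arrhenius_simple() -> ArrheniusParams:
    """Arrhenius parameters of the isolated 2-spin analysis."""
    return ArrheniusParams(ea=3.05, tau0=1.3e-12)


#: Per-temperature best-fit parameters of the three-population model:
#: as (T, n_B, sigma, S^2) tuples.
BATH_FIT_PARAMS = [
    (268.0, 2.7, 0.70, 0.93),
    (233.0, 1.9, 1.1, 0.95),
    (198.0, 1.7, 1.3, 0.94),
    (178.0, 1.2, 1.4, 0.91),
    (149.0, 0.70, 0.85, 0.93),
]

#: Fast-component amplitudes predicted by the spin-diffusion (bath) model
#: at the five temperatures, as (T, alpha) tuples.
BATH_MODEL_ALPHA = [
    (268.0, 0.58),
    (233.0, 0.71),
    (198.0, 0.77),
    (178.0, 0.70),
    (149.0, 0.23),
]

#: Fast-component amplitudes predicted by the isolated 2-spin model.
ISOLATED_MODEL_ALPHA = [
    (268.0, 0.85),
    (233.0, 0.96),
    (198.0, 1.0),
    (178.0, 1.0),
    (149.0, 1.0),
]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
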