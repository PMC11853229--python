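import numpy as np
import pytest

from celleis import constants as C
from celleis import ecm, lpm
from celleis.spectra import default_grid


@pytest.fixture(scope="session")
def ref_medium() -> ecm.MediumProperties:
    """Medium of the calibrated reference unit (0.9 S/m, eps_r 81)."""
    return ecm.MediumProperties(
        sigma_m=C.SIGMA_M_REFERENCE, eps_r_m=C.EPS_R_MEDIUM_REFERENCE
    )


@pytest.fixture(scope="session")
def ref_geom() -> ecm.SensingUnitGeometry:
    return ecm.SensingUnitGeometry(g_f=C.GF_REFERENCE)


@pytest.fixture(scope="session")
def grid100() -> np.ndarray:
    """The standard 100-point log sweep, 10 kHz to 10 MHz."""
    return default_grid()


@pytest.fixture(scope="session")
def ref_unit_params(ref_medium) -> dict:
    return {
        "medium": ref_medium,
        "g_f": C.GF_REFERENCE,
        "c_dl": C.CDL_REFERENCE,
    }


@pytest.fixture(scope="session")
def chain() -> lpm.PeripheralParams:
    """Study-condition measurement chain: micro-henry wires, tens of ohms,
    picofarad parasitics around a 100 kOhm transimpedance stage."""
    return lpm.PeripheralParams(
        c_p=5e-12, l_w=1e-6, r_w=50.0, r_ac=100e3, c_ac=2e-12,
        l_r=1e-6, c_r=10e-12,
    )


def random_components(rng: np.random.Generator, with_cell: bool) -> ecm.ECMComponents:
    """Valid random component draws spanning realistic decades."""
    kw = dict(
        r_m=10 ** rng.uniform(4, 6),
        c_m=10 ** rng.uniform(-15, -12),
        c_dl=10 ** rng.uniform(-12, -10),
        phi=10 ** rng.uniform(-4, -1),
    )
    if with_cell:
        kw["r_c"] = 10 ** rng.uniform(5, 8)
        kw["c_mem"] = 10 ** rng.uniform(-15, -12)
    return ecm.ECMComponents(**kw)
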