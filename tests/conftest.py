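import numpy as np
import pytest

import bilayerdos as bd


@pytest.fixture(scope="session")
def table():
    return bd.load_default_extinction()


@pytest.fixture(scope="session")
def instrument():
    return bd.InstrumentSpec()


@pytest.fixture(scope="session")
def coarse_instrument():
    """Reduced CW grid (2 nm step) for tests where the full 749-point
    broadband grid adds runtime but no coverage."""
    return bd.InstrumentSpec(cw_wavelengths=np.arange(650.0, 1024.0 + 1e-9, 2.0))


@pytest.fixture(scope="session")
def baseline():
    return bd.baseline_medium()


@pytest.fixture(scope="session")
def baseline_data(baseline, instrument, table):
    return bd.simulate_instrument(baseline, instrument, table)


@pytest.fixture(scope="session")
def baseline_rec(baseline_data, instrument, table):
    return bd.recover_all(baseline_data, instrument, table)


@pytest.fixture(scope="session")
def baseline_matrix(baseline, instrument, table, baseline_rec):
    return bd.sensitivity_matrix(baseline, instrument, table, baseline_rec=baseline_rec)


def random_homogeneous_medium(rng) -> bd.TwoLayerMedium:
    """A homogeneous medium drawn inside the study's baseline parameter ranges."""
    c = bd.ChromophoreConcentrations(
        thb_uM=rng.uniform(12.0, 120.0),
        so2=rng.uniform(0.67, 0.83),
        water=rng.uniform(0.05, 0.90),
        lipid=rng.uniform(0.20, 0.70),
    )
    s = bd.ScatteringLaw(musp830=rng.uniform(0.40, 0.60), power=rng.uniform(0.1, 1.5))
    layer = bd.Layer(c, s)
    return bd.TwoLayerMedium(top=layer, bottom=layer, z_top_mm=rng.uniform(2.0, 10.0))
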