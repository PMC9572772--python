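import numpy as np
import pytest

from ctclab.datasets import critical_points
from ctclab.synth import SimulationSpec, gen_hbond_dimer


@pytest.fixture(scope="session")
def reference_cps():
    """Published BCP descriptor rows for both complexes."""
    return critical_points()


@pytest.fixture(scope="session")
def water_dimer():
    return gen_hbond_dimer(1.9)


@pytest.fixture
def excess_acceptor_spec():
    """Noiseless titration design with acceptor in >=100-fold excess,
    where the Benesi-Hildebrand linearisation is essentially exact."""
    return SimulationSpec(
        kc_true=1e4, epsilon_c=5e3, donor_conc_M=1e-6,
        acceptor_conc_M=tuple(np.linspace(1e-4, 1e-3, 8)),
    )
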