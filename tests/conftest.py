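import numpy as np
import pytest

from mixedsyn.network_builder import build_size_network
from mixedsyn.protocols import run_convergence_sweep, run_coupling_map

# analytic passive constants of the default membrane (c_m = 1 uF/cm^2,
# g_leak = 0.3 mS/cm^2): tau = c_m/g_leak, Rin(d) = 1/(g_leak * pi * d^2)
TAU_MS = 1.0 / 0.3


def analytic_rin_mohm(diameter_um: float) -> float:
    g_ns = 0.3 * np.pi * (diameter_um * 1e-4) ** 2 * 1e6
    return 1e3 / g_ns


@pytest.fixture(scope="session")
def convergence_sweep():
    """Full 10-diameter x {0,1,5,10} duplication sweep (shared chem wiring)."""
    return run_convergence_sweep([0, 1, 5, 10])


@pytest.fixture(scope="session")
def coupling_map():
    """Coupling-potential map at full convergence with dedicated chem inputs."""
    net = build_size_network(10, chem_wiring="dedicated")
    return run_coupling_map(net)
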