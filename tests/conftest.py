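import numpy as np
import pytest

from ungflex.synthetic import SimSpec, gen_tcspc
from ungflex.tcspc import fit_two_window

#: Ground-truth lifetimes used across the TCSPC tests (ns).
TRUE_TAUS_NS = np.array([0.03, 0.4, 1.5, 8.0])


@pytest.fixture(scope="session")
def tcspc_sim():
    """One Poisson-noise two-window decay set at the default study conditions."""
    return gen_tcspc(SimSpec(seed=11, stage="tcspc"))


@pytest.fixture(scope="session")
def tcspc_fit(tcspc_sim):
    """Two-window global fit of the shared simulation (reused: it is the
    single most expensive computation in the suite)."""
    return fit_two_window(
        tcspc_sim.short_decays,
        tcspc_sim.long_decays,
        tcspc_sim.irf_short,
        tcspc_sim.irf_long,
    )
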