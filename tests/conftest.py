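import numpy as np
import pytest

import mstdpnet as m


@pytest.fixture(scope="session")
def bars8():
    return m.make_bars_dataset(8)


@pytest.fixture()
def plast_params():
    return m.PlasticityParams(eta=1e-3, zeta=1e-3, tau_plus=20.0, tau_minus=20.0, w_max=1.0)


@pytest.fixture(scope="session")
def frozen_records():
    """Seeded Poisson spike records, 10 visible x 5 hidden, 30 ms."""
    return m.make_frozen_spike_records(
        n_vis=10, n_hid=5, rate=0.2, duration=30.0, count=50, seed=42
    )


def brute_force_stdp(pre, post, tau_plus, tau_minus):
    """Independent O(n^2) double-loop pair sum: potentiation when the
    post spike is strictly later, depression otherwise."""
    total = 0.0
    for tk in pre:
        for tl in post:
            if tl > tk:
                total += np.exp(-abs(tl - tk) / tau_plus)
            else:
                total -= np.exp(-abs(tl - tk) / tau_minus)
    return total


@pytest.fixture(scope="session")
def brute_stdp():
    return brute_force_stdp
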