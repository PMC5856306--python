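"""Shared phantom fixtures.

All fixtures are generated programmatically; session scope keeps the more
expensive simulated studies shared across test modules.
"""

import numpy as np
import pytest

import rflesion as rf

TES = np.array([3.0, 25.0, 75.0, 184.0])


@pytest.fixture(scope="session")
def noiseless_config():
    return rf.PhantomConfig(snr=np.inf,
                            lesion=rf.LesionSpec(target_volume_mL=0.48))


@pytest.fixture(scope="session")
def noiseless_label(noiseless_config):
    return rf.build_label_volume(noiseless_config, 10.0)


@pytest.fixture(scope="session")
def noiseless_t2map(noiseless_config, noiseless_label):
    series = rf.simulate_t2prep_series(noiseless_label, noiseless_config)
    return rf.fit_t2_map(series, noiseless_label.myocardium_region)


@pytest.fixture(scope="session")
def noisy_config():
    return rf.PhantomConfig(snr=30.0, seed=11,
                            lesion=rf.LesionSpec(target_volume_mL=0.48))


@pytest.fixture(scope="session")
def noisy_label(noisy_config):
    return rf.build_label_volume(noisy_config, 10.0)


@pytest.fixture(scope="session")
def noisy_t2map(noisy_config, noisy_label):
    series = rf.simulate_t2prep_series(noisy_label, noisy_config, seed=17)
    return rf.fit_t2_map(series, noisy_label.myocardium_region)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
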