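import numpy as np
import pytest

import cmefit as cf


@pytest.fixture(scope="session")
def birth_death():
    return cf.builtin_model("birth_death_test")


@pytest.fixture(scope="session")
def ecoli():
    return cf.builtin_model("ecoli_rna")


@pytest.fixture(scope="session")
def toggle():
    return cf.builtin_model("toggle_switch")


@pytest.fixture(scope="session")
def ecoli_dataset():
    """Moderate-size mRNA-counting dataset shared across estimation tests."""
    return cf.generate_case_study("ecoli_rna", m=10_000, seed=20_240)


def two_bin_pair():
    """The hand-checked two-bin PDF pair: data (0.6, 0.4) vs model (0.5, 0.5)."""
    scheme = cf.BinningScheme([0.0, 1.0, 2.0])
    data = cf.BinnedDensity("pdf", scheme, np.array([0.6, 0.4]), 100)
    model = cf.BinnedDensity("pdf", scheme, np.array([0.5, 0.5]), 100)
    return data, model
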