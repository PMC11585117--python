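import dataclasses

import numpy as np
import pytest

import mokl


@pytest.fixture(scope="session")
def scenario_a():
    """One informative block, two noise blocks; binary, n=200, seed 0."""
    return mokl.generate(mokl.preset("A"))


@pytest.fixture(scope="session")
def scenario_b():
    """Concentric radial classes in every block; binary, n=400, seed 0."""
    return mokl.generate(mokl.preset("B"))


@pytest.fixture(scope="session")
def scenario_c():
    """Imbalanced 3-class task; n=300, seed 0."""
    return mokl.generate(mokl.preset("C"))


@pytest.fixture(scope="session")
def scenario_a300():
    """Scenario A scaled to n=300 (interpretability recovery conditions)."""
    spec = dataclasses.replace(mokl.preset("A"), n=300)
    return mokl.generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_kernel(rng, n, rank=None):
    """Random PSD matrix wrapped as a KernelMatrix (linear-kernel provenance)."""
    rank = rank or n
    X = rng.normal(size=(n, rank))
    return mokl.linear_kernel(X)


@pytest.fixture
def psd_factory(rng):
    return lambda n, rank=None: random_psd_kernel(rng, n, rank)
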