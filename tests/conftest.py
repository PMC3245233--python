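import warnings

import numpy as np
import pytest

import ratemix as rm


@pytest.fixture(autouse=True)
def _quiet_optimizer_warnings():
    """Optimisation round-limit warnings are expected at toy scales."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        warnings.filterwarnings("ignore", message=".*round limit.*")
        yield


@pytest.fixture(scope="session")
def protein():
    return rm.protein_alphabet()


@pytest.fixture(scope="session")
def alpha4():
    return rm.toy_alphabet(4)


def random_model(alphabet, rng, uniform_pi=False):
    """A random reversible (S, pi, Q) triple with mean rate 1."""
    n_free = rm.free_parameter_count(alphabet)
    S = rm.unflatten_exchangeabilities(rng.lognormal(0, 1, n_free), alphabet)
    if uniform_pi:
        pi = rm.FrequencyVector.uniform(alphabet)
    else:
        w = rng.random(alphabet.size) + 0.2
        pi = rm.FrequencyVector(alphabet, w / w.sum())
    return S, pi, rm.build_rate_matrix(S, pi, normalize=True)


@pytest.fixture(scope="session")
def model4(alpha4):
    return random_model(alpha4, np.random.default_rng(1))


@pytest.fixture(scope="session")
def small_dataset(alpha4, model4):
    """A 6-taxon tree and a 200-site alignment simulated under model4."""
    _, _, Q = model4
    tree = rm.random_tree(6, np.random.default_rng(2))
    aln = rm.simulate_alignment(rm.SimulationConfig(tree, Q, 200, seed=3))
    return aln, tree, Q
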