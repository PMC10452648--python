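import numpy as np
import pytest

import gadnet
from gadnet import gad7
from gadnet import glasso as _gl


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    # pay the numba compilation cost once, outside timed assertions
    _gl.warmup()


@pytest.fixture(scope="session")
def published_net():
    return gad7.published_network()


@pytest.fixture(scope="session")
def reference_truth():
    return gadnet.reference_ggm_truth(seed=1)


@pytest.fixture(scope="session")
def cohort_2000(reference_truth):
    """Unfiltered 4-level responses from the reference GGM truth, n=2000."""
    cfg = gadnet.default_config(n=2000, inclusion_min_total=None)
    return gadnet.sample_likert_from_ggm(reference_truth, cfg, seed=11)


@pytest.fixture(scope="session")
def cohort_5000(reference_truth):
    cfg = gadnet.default_config(n=5000, inclusion_min_total=None)
    return gadnet.sample_likert_from_ggm(reference_truth, cfg, seed=12)


def random_positive_network(p, rng, density=0.5):
    """Connected random network with positive weights (test helper)."""
    while True:
        w = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < density:
                    w[i, j] = w[j, i] = rng.uniform(0.05, 0.4)
        net = gadnet.SymptomNetwork(weights=w)
        deg = (w > 0).sum(axis=1)
        if np.all(deg > 0):
            try:
                gadnet.spinglass_partition(net, seed=0, restarts=1)
                return net
            except ValueError:
                continue
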