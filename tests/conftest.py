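import numpy as np
import pytest

from nucfree.io_formats import GenomeSequence, WeightMatrix
from nucfree.thermo_core import BindingWeights


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_wm():
    """2-position matrix used in hand-worked energy examples."""
    return WeightMatrix("toy", np.array([[0.5, 0.25, 0.125, 0.125],
                                         [0.7, 0.1, 0.1, 0.1]]))


@pytest.fixture
def random_genome(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return GenomeSequence("chr1", seq)


def random_instance(rng, L_max=30, n_factors_max=3, max_configs=300_000):
    """A random small binding-weights instance for oracle comparisons,
    resampled until exhaustive enumeration is cheap."""
    from nucfree.thermo_core import _count_configurations

    while True:
        L = int(rng.integers(10, L_max + 1))
        nf = int(rng.integers(1, n_factors_max + 1))
        footprints = rng.integers(2, 8, size=nf)
        weights = []
        for l in footprints:
            n = max(L - int(l) + 1, 0)
            w = rng.random(n) * np.exp(rng.normal(0, 2))
            w[rng.random(n) < 0.2] = 0.0
            weights.append(w)
        names = [f"f{i}" for i in range(nf)]
        bw = BindingWeights.from_arrays(names, [int(l) for l in footprints], weights, L)
        if _count_configurations(bw) <= max_configs:
            return bw
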