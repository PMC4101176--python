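import numpy as np
import pytest

import aimeval as av


@pytest.fixture(scope="session")
def three_pop_sim():
    """Three drifted populations, 30 individuals each, 800 loci."""
    cfg = av.SimulationConfig(L=800, n_per_pop=30, seed=11)
    freqs, gm = av.simulate_dataset(cfg)
    return cfg, freqs, gm


@pytest.fixture(scope="session")
def est_freqs(three_pop_sim):
    _, _, gm = three_pop_sim
    return av.estimate_frequencies(gm)


def make_gm(G, pop_labels=None, loci=None):
    G = np.asarray(G)
    n, l = G.shape
    return av.GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=loci or [f"rs{j}" for j in range(l)],
        G=G,
        pop_labels=pop_labels,
    )
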