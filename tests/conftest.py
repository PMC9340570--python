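import numpy as np
import pytest

import grnspa as g


@pytest.fixture
def small_system():
    """A 20-gene stable network with its design and noise-free expression."""
    net = g.generate_true_network(20, sparsity=2.0, tf_fraction=0.5, seed=7)
    design = g.make_design(20, replicates=3)
    clean = g.simulate_expression(net, design, perturbation_strength=3.0)
    return net, design, clean


@pytest.fixture
def toy_network():
    """3-gene cascade with hand-invertible weights."""
    a = np.array([[-1.0, 0.0, 0.0], [0.5, -1.0, 0.0], [0.0, 0.5, -1.0]])
    return g.GeneNetwork(["G1", "G2", "G3"], a)
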