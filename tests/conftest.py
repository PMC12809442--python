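"""Shared fixtures: synthetic models, traces and the default alphabet."""

import numpy as np
import pytest

from saqc import alphabet, synthetic
from saqc.io_structures import extract_ca_trace

#: mixed secondary-structure plan used by several fixture factories;
#: roughly the helix/strand/coil balance of a small folded protein
MIXED_SEGMENTS = [("helix", 20), ("coil", 8), ("strand", 14), ("coil", 6), ("helix", 8)]


@pytest.fixture(scope="session")
def params():
    return alphabet.default_parameters()


@pytest.fixture(scope="session")
def helix_model():
    return synthetic.build_chain(synthetic.BuildSpec(n_residues=30, seed=7))


@pytest.fixture(scope="session")
def helix_trace(helix_model):
    return extract_ca_trace(helix_model, "A")


@pytest.fixture(scope="session")
def mixed_model():
    return synthetic.build_chain(
        synthetic.BuildSpec(n_residues=56, segments=MIXED_SEGMENTS, seed=11)
    )


@pytest.fixture
def perturbed_pair():
    """Factory: (reference, perturbed, target index, delta) for a given seed."""

    def make(seed, target=None, delta=None, dihedral="psi"):
        rng = np.random.default_rng(seed)
        spec = synthetic.BuildSpec(n_residues=56, segments=MIXED_SEGMENTS, seed=seed)
        model = synthetic.build_chain(spec)
        if target is None:
            target = int(rng.integers(5, 50))
        if delta is None:
            delta = float(rng.uniform(20, 60)) * (1 if rng.random() < 0.5 else -1)
        pert = synthetic.perturb(
            model, synthetic.PerturbSpec([(target, dihedral, delta)])
        )
        return model, pert, target, delta

    return make


def random_fragment_pair(rng, spread=4.0):
    """Two random non-degenerate 4-point fragments."""
    return (
        rng.uniform(-spread, spread, (4, 3)),
        rng.uniform(-spread, spread, (4, 3)),
    )
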