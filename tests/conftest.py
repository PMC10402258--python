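import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from morphoscale import core, synth


def make_tree(coords, parents, radii=None, structure=None):
    """Small-tree helper: parents are 0-based indices (None for root)."""
    n = len(coords)
    return core.NeuronTree(
        np.arange(1, n + 1),
        structure if structure is not None else [1] + [3] * (n - 1),
        np.array(coords, float),
        radii if radii is not None else [1.0] * n,
        [(-1 if p is None else p + 1) for p in parents],
    )


@pytest.fixture
def y_neuron():
    """Soma(0,0,0) → (10,0,0) → (20,0,0), bifurcating to (20,±10,0)."""
    return make_tree(
        [(0, 0, 0), (10, 0, 0), (20, 0, 0), (20, 10, 0), (20, -10, 0)],
        [None, 0, 1, 2, 2],
        radii=[5, 0.5, 0.5, 0.5, 0.5],
        structure=[1, 3, 3, 3, 3],
    )


def random_tree(rng, n_nodes=30, step=8.0):
    """Random rooted tree grown by attaching nodes to random parents."""
    coords = [np.zeros(3)]
    parents = [None]
    for _ in range(n_nodes - 1):
        p = int(rng.integers(len(coords)))
        coords.append(coords[p] + rng.normal(0, step, 3))
        parents.append(p)
    radii = rng.uniform(0.3, 2.0, n_nodes)
    return make_tree(coords, parents, radii=list(radii))


def random_binary_tree(rng, max_depth=5, step=10.0):
    """Strictly binary random tree (every internal node has 0 or 2 kids)."""
    coords = [np.zeros(3)]
    parents = [None]

    def grow(idx, depth):
        if depth >= max_depth or rng.random() < 0.3:
            return
        for _ in range(2):
            coords.append(coords[idx] + rng.normal(0, step, 3))
            parents.append(idx)
            grow(len(coords) - 1, depth + 1)

    coords.append(coords[0] + rng.normal(0, step, 3))
    parents.append(0)
    grow(1, 0)
    return make_tree(coords, parents)


@pytest.fixture
def toy_atlas():
    return synth.make_toy_atlas(synth.SynthSpec(seed=0))


@pytest.fixture
def default_spec():
    return synth.SynthSpec(seed=0)
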