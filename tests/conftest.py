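import numpy as np
import pytest

from microcortex.morphology import NeuriteTree, NeuronMorphology, NeuronMeta
from microcortex.synthetic import human_like, mouse_like, generate_population


def chain_tree(length=100.0, n_nodes=11, neurite_type="basal", diameter=0.5, direction=(0, 1, 0)):
    """Straight unbranched neurite of the given total length."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    step = length / (n_nodes - 1)
    pts = np.outer(np.arange(n_nodes) * step, direction)
    parent = np.arange(-1, n_nodes - 1)
    return NeuriteTree(parent, pts, np.full(n_nodes, diameter), neurite_type)


def y_tree(trunk=50.0, child_a=50.0, child_b=30.0, neurite_type="basal"):
    """Bifurcating tree: trunk then two straight children (total path
    lengths trunk+child_a and trunk+child_b)."""
    pts = [
        (0, 0, 0),
        (0, trunk, 0),
        (child_a / np.sqrt(2), trunk + child_a / np.sqrt(2), 0),
        (-child_b / np.sqrt(2), trunk + child_b / np.sqrt(2), 0),
    ]
    parent = np.array([-1, 0, 1, 1])
    return NeuriteTree(parent, np.array(pts, float), np.full(4, 0.5), neurite_type)


def comb_axon(n_branches, tooth=20.0, spacing=15.0):
    """Axon with an exact odd branch count 2*teeth+1 (teeth bifurcations)."""
    assert n_branches % 2 == 1 and n_branches >= 3
    teeth = (n_branches - 1) // 2
    parent, pts = [-1], [(0.0, 0.0, 0.0)]
    spine_idx = 0
    for t in range(teeth):
        parent.append(spine_idx)
        pts.append((0.0, -(t + 1) * spacing, 0.0))
        spine_idx = len(parent) - 1
        parent.append(spine_idx)
        pts.append((tooth, -(t + 1) * spacing, 0.0))
    parent.append(spine_idx)  # final spine leaf, so every tooth bifurcates
    pts.append((0.0, -(teeth + 1) * spacing, 0.0))
    return NeuriteTree(np.array(parent), np.array(pts), np.full(len(parent), 0.8), "axon")


def simple_neuron(trees=None, cell_class="PC", soma_radius=5.0):
    if trees is None:
        trees = [chain_tree()]
    return NeuronMorphology(
        np.zeros(3), soma_radius, trees, NeuronMeta(cell_class=cell_class)
    )


@pytest.fixture(scope="session")
def human_preset():
    return human_like()


@pytest.fixture(scope="session")
def mouse_preset():
    return mouse_like()


@pytest.fixture(scope="session")
def human_pc_pop(human_preset):
    return generate_population(human_preset, 8, seed=101, cell_class="PC")


@pytest.fixture(scope="session")
def mouse_pc_pop(mouse_preset):
    return generate_population(mouse_preset, 8, seed=102, cell_class="PC")
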