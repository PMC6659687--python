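import numpy as np
import pytest

from matrophylo.simulate import simulate_bd_tree
from matrophylo.trees import TimeTree


@pytest.fixture
def cherry():
    return TimeTree.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return TimeTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip():
    return TimeTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def bd_tree_50():
    tree, _ = simulate_bd_tree(0.25, 0.08, ("n_tips", 50), seed=421)
    return tree


@pytest.fixture(scope="session")
def bd_tree_100():
    tree, _ = simulate_bd_tree(0.2, 0.05, ("n_tips", 100), seed=73)
    return tree


def random_topology(rng, n_tips, depth_scale=1.0):
    """Random ultrametric tree by coalescent-style pairwise joins."""
    nodes = [f"T{i}" for i in range(n_tips)]
    heights = {lab: 0.0 for lab in nodes}
    newicks = {lab: lab for lab in nodes}
    h = 0.0
    while len(nodes) > 1:
        h += depth_scale * rng.exponential(1.0 / len(nodes))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({newicks[a]}:{h - heights[a]:.10g},{newicks[b]}:{h - heights[b]:.10g})"
        lab = a + b
        for x in sorted((i, j), reverse=True):
            nodes.pop(x)
        nodes.append(lab)
        newicks[lab] = merged
        heights[lab] = h
    return TimeTree.from_newick(newicks[nodes[0]] + ";")
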