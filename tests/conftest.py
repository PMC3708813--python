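import itertools

import numpy as np
import pytest
import scipy.linalg

import coevoscan as cs


@pytest.fixture
def small_tree():
    """4-leaf tree with mixed branch lengths."""
    return cs.load_tree("((a:0.3,b:0.5):0.2,(c:0.4,d:0.1):0.6);")


@pytest.fixture(scope="session")
def tree200():
    """200-leaf Yule tree shared by the heavier fitting tests."""
    return cs.simulate_tree(200, seed=11)


def enumeration_loglik(tree, tips, rates8, root_prior=None):
    """Independent oracle: likelihood by exhaustive summation over all
    ancestral state assignments, with per-branch scipy matrix exponentials.

    Exponential in the number of internal nodes; only usable on tiny trees.
    """
    Q = cs.build_generator(np.asarray(rates8, dtype=float))
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = list(tree.tree.leaf_node_iter())
    prior = np.full(4, 0.25) if root_prior is None else np.asarray(root_prior)
    leaf_state = dict(zip([l.taxon.label for l in leaves], np.asarray(tips)))
    P_edge = {
        id(n): scipy.linalg.expm(Q * n.edge.length)
        for n in nodes
        if n.parent_node is not None
    }
    root = nodes[-1]
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        for l in leaves:
            amap[id(l)] = int(leaf_state[l.taxon.label])
        p = prior[amap[id(root)]]
        for n in nodes:
            if n.parent_node is None:
                continue
            p *= P_edge[id(n)][amap[id(n.parent_node)], amap[id(n)]]
        total += p
    return float(np.log(total))


def random_topology_newick(n_leaves: int, rng: np.random.Generator) -> str:
    """Random binary tree built by sequential joining, random branch
    lengths in (0.05, 1.0)."""
    subtrees = [f"t{i}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        la, lb = rng.uniform(0.05, 1.0, size=2)
        subtrees.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    root_children = subtrees[0]
    return root_children + ";"
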