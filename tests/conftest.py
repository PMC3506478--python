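import numpy as np
import pytest

from evosite.phylo.model import SubstitutionModel
from evosite.phylo.tree import Node, PhyloTree


@pytest.fixture(scope="session")
def toy4_model():
    """Reversible 4-state toy model with unequal frequencies."""
    rng = np.random.default_rng(7)
    S = rng.uniform(0.5, 2.0, size=(4, 4))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0.0)
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    return SubstitutionModel("ACGT", S, pi)


@pytest.fixture
def tree4():
    """((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1); rooted, 3 internal nodes."""
    root = Node()
    left = Node(length=0.05)
    right = Node(length=0.1)
    left.add_child(Node("A", 0.1))
    left.add_child(Node("B", 0.2))
    right.add_child(Node("C", 0.3))
    right.add_child(Node("D", 0.15))
    root.add_child(left)
    root.add_child(right)
    return PhyloTree(root)


def make_random_tree(n_leaves, rng, max_len=0.4):
    """Random rooted binary tree with uniform branch lengths."""
    nodes = [Node(name=f"L{i}", length=float(rng.uniform(0.01, max_len)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(0.01, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [parent]
    root = Node()
    for n in nodes:
        root.add_child(n)
    return PhyloTree(root)


def brute_force_site_loglik(tree, leaf_codes, model, scale=1.0):
    """Sum over all internal-node state assignments (enumeration oracle)."""
    from scipy.linalg import expm

    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = tree.leaves()
    n_states = model.n_states
    n_sites = len(next(iter(leaf_codes.values())))
    P = {id(n): expm(model.Q * (n.length or 0.0) * scale)
         for n in tree.postorder() if n.parent is not None}

    out = np.zeros(n_sites)
    for site in range(n_sites):
        total = 0.0
        assign = {}

        def rec(k):
            nonlocal total
            if k == len(internals):
                p = model.frequencies[assign[id(tree.root)]]
                for node in tree.postorder():
                    if node.parent is None:
                        continue
                    s_par = assign[id(node.parent)]
                    if node.is_leaf:
                        code = leaf_codes[node.name][site]
                        if code < 0:
                            continue
                        p *= P[id(node)][s_par, code]
                    else:
                        p *= P[id(node)][s_par, assign[id(node)]]
                total += p
                return
            for s in range(n_states):
                assign[id(internals[k])] = s
                rec(k + 1)

        rec(0)
        out[site] = np.log(total)
    return out
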