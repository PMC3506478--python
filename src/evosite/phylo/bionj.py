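"""BIONJ distance-based tree construction (variance-weighted neighbor joining).

Exact on additive metrics; ties in the pair-selection criterion are broken by
label order so output is deterministic.
"""

from __future__ import annotations

import numpy as np

from .tree import Node, PhyloTree


def bionj(dist, labels) -> PhyloTree:
    D = np.asarray(dist, dtype=float).copy()
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be square symmetric with zero diagonal")
    if np.any(D < 0):
        raise ValueError("negative distances")

    V = D.copy()
    nodes = [Node(name=lab) for lab in labels]
    # sort key for deterministic tie-breaks: smallest leaf label under a node
    keys = list(labels)
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        S = sub.sum(axis=1)
        Qc = (r - 2) * sub - S[:, None] - S[None, :]
        np.fill_diagonal(Qc, np.inf)

        # argmin with deterministic tie-break by (key_i, key_j)
        qmin = Qc.min()
        cand = np.argwhere(np.isclose(Qc, qmin, rtol=0, atol=1e-12))
        best = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((keys[idx[ab[0]]], keys[idx[ab[1]]]))),
        )
        ai, bi = best
        i, j = idx[ai], idx[bi]

        d_ij = D[i, j]
        b_i = 0.5 * d_ij + (S[ai] - S[bi]) / (2.0 * (r - 2))
        b_j = d_ij - b_i
        b_i, b_j = max(b_i, 0.0), max(b_j, 0.0)

        others = [k for k in active if k != i and k != j]
        if V[i, j] > 0 and others:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (
                2.0 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = Node()
        nodes[i].length = b_i
        nodes[j].length = b_j
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        # reuse slot i for the new node
        for k in others:
            D[i, k] = D[k, i] = lam * (D[i, k] - b_i) + (1 - lam) * (D[j, k] - b_j)
            V[i, k] = V[k, i] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * V[i, j]
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    # closing trifurcation by three-point formulas
    a, b, c = sorted(active, key=lambda k: keys[k])
    root = Node()
    nodes[a].length = max(0.0, 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    nodes[b].length = max(0.0, 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    nodes[c].length = max(0.0, 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    for k in (a, b, c):
        root.add_child(nodes[k])
    return PhyloTree(root)
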