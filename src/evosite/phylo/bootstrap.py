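"""Nonparametric bootstrap support for tree bipartitions."""

from __future__ import annotations

import numpy as np

from ..seqio import MultipleAlignment
from .tree import PhyloTree


def resample_columns(aln: MultipleAlignment, rng: np.random.Generator) -> MultipleAlignment:
    cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
    recs = [(rid, "".join(row[c] for c in cols)) for rid, row in aln.records]
    return MultipleAlignment(recs, aln.alphabet, aln.origin_offset)


def bootstrap_support(aln: MultipleAlignment, tree_builder, n_replicates: int,
                      seed: int, reference_tree: PhyloTree | None = None):
    """Bipartition support proportions over ``n_replicates`` column resamples.

    ``tree_builder`` maps an alignment to a PhyloTree.  Returns a dict
    split -> support; if ``reference_tree`` is given its internal nodes are
    annotated in place and the dict is restricted to its splits.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        rep_tree = tree_builder(resample_columns(aln, rng))
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    support = {s: c / n_replicates for s, c in counts.items()}

    if reference_tree is not None:
        all_leaves = frozenset(reference_tree.leaf_names())
        for node in reference_tree.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = frozenset(l.name for l in _leaves_under(node))
            key = min(side, all_leaves - side, key=lambda s: tuple(sorted(s)))
            node.support = support.get(key, 0.0)
        support = {s: v for s, v in support.items()
                   if s in reference_tree.bipartitions()}
    return support


def _leaves_under(node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out
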