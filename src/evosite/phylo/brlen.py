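"""Branch-length optimization on a fixed topology (coordinate-wise Brent)."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .distance import D_MAX
from .likelihood import (encode_codon_leaf_codes, encode_leaf_codes,
                         prune_site_loglik)
from ..seqio import CodonAlignment


def _leaf_codes_for(tree, aln, model):
    if isinstance(aln, CodonAlignment):
        codes = encode_codon_leaf_codes(aln)
    else:
        codes = encode_leaf_codes(aln, model)
    return {name: codes[name] for name in tree.leaf_names()}


def optimize_branch_lengths(tree, aln, model, tol: float = 1e-6,
                            max_sweeps: int = 20, xatol: float = 1e-8):
    """Return a copy of ``tree`` with branch lengths optimized one at a time.

    Total log-likelihood is non-decreasing at every accepted update; sweeps
    stop when a full pass improves the log-likelihood by less than ``tol``.
    """
    from .likelihood import compress_patterns

    tree = tree.copy()
    codes, weights, _ = compress_patterns(_leaf_codes_for(tree, aln, model))

    def total(tr):
        return float(prune_site_loglik(tr, codes, model) @ weights)

    current = total(tree)
    for _ in range(max_sweeps):
        start = current
        for node in tree.branches():
            old = node.length or 0.0

            def neg(t, node=node):
                node.length = t
                return -total(tree)

            res = minimize_scalar(neg, bounds=(0.0, D_MAX), method="bounded",
                                  options={"xatol": xatol})
            if -res.fun > current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = old
        if current - start < tol:
            break
    return tree
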