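"""Felsenstein pruning over arbitrary finite state spaces.

Gaps and ambiguity codes carry all-ones partial likelihoods (fully missing).
Per-site log-likelihoods are returned so mixture models can reweight sites.
"""

from __future__ import annotations

import numpy as np

from ..seqio import CodonAlignment, MultipleAlignment, SENSE_CODONS, CODON_INDEX
from .model import SubstitutionModel
from .tree import PhyloTree


def encode_leaf_codes(aln: MultipleAlignment, model: SubstitutionModel) -> dict[str, np.ndarray]:
    """Per-identifier integer state codes; -1 marks gap/ambiguity."""
    return {rid: model.encode(row) for rid, row in aln.records}


def encode_codon_leaf_codes(caln: CodonAlignment) -> dict[str, np.ndarray]:
    """Codes into the 61 sense codons; gaps and N-containing codons are -1."""
    out = {}
    for rid, codons in caln.codon_rows():
        out[rid] = np.array([CODON_INDEX.get(c, -1) for c in codons], dtype=np.int64)
    return out


def compress_patterns(leaf_codes: dict[str, np.ndarray]):
    """Collapse identical site patterns.

    Returns (compressed leaf codes, pattern weights, inverse index) so that
    per-site quantities expand as ``values[inverse]``.
    """
    names = sorted(leaf_codes)
    mat = np.stack([leaf_codes[n] for n in names], axis=1)  # (sites, taxa)
    uniq, inverse, counts = np.unique(mat, axis=0, return_inverse=True,
                                      return_counts=True)
    comp = {n: uniq[:, i].copy() for i, n in enumerate(names)}
    return comp, counts.astype(float), inverse


def prune_site_loglik(tree: PhyloTree, leaf_codes: dict[str, np.ndarray],
                      model: SubstitutionModel, scale: float = 1.0) -> np.ndarray:
    """Per-site log-likelihood by postorder pruning.

    ``scale`` multiplies every branch length (site-rate or global scaling).
    """
    if scale <= 0:
        raise ValueError("rate/scale must be positive")
    n_states = model.n_states
    n_sites = len(next(iter(leaf_codes.values())))
    eye = np.eye(n_states)

    partial: dict[int, np.ndarray] = {}
    log_scaler = np.zeros(n_sites)

    for node in tree.postorder():
        if node.is_leaf:
            codes = leaf_codes[node.name]
            L = np.where(codes[:, None] >= 0, eye[np.clip(codes, 0, None)], 1.0)
        else:
            L = np.ones((n_sites, n_states))
            for child in node.children:
                t = (child.length or 0.0) * scale
                if not np.isfinite(t):
                    raise ValueError("non-finite branch length")
                P = model.transition_matrix(t)
                L = L * (partial.pop(id(child)) @ P.T)
            mx = L.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            L = L / safe[:, None]
            with np.errstate(divide="ignore"):
                log_scaler += np.log(mx)  # -inf when a site is impossible
        partial[id(node)] = L

    root_L = partial[id(tree.root)]
    lik = root_L @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.log(lik) + log_scaler


def site_log_likelihoods(tree: PhyloTree, aln, model: SubstitutionModel,
                         rate: float = 1.0) -> np.ndarray:
    """Public per-site log-likelihood for an alignment (plain or codon)."""
    if isinstance(aln, CodonAlignment):
        codes = encode_codon_leaf_codes(aln)
        ids = aln.identifiers
    else:
        codes = encode_leaf_codes(aln, model)
        ids = aln.identifiers
    missing = set(tree.leaf_names()) - set(ids)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    codes = {name: codes[name] for name in tree.leaf_names()}
    return prune_site_loglik(tree, codes, model, scale=rate)


def total_log_likelihood(tree, aln, model, rate: float = 1.0) -> float:
    return float(site_log_likelihoods(tree, aln, model, rate).sum())
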