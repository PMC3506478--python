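"""Joint maximum-likelihood ancestral codon reconstruction.

Max-product dynamic programming up the tree with a backtrace down; the
reconstruction is the single most probable simultaneous assignment of codons
to all internal nodes.  Ties break toward the lowest codon index, so outputs
are deterministic.
"""

from __future__ import annotations

import numpy as np

from ..phylo.likelihood import encode_codon_leaf_codes
from ..phylo.model import SubstitutionModel
from ..seqio import SENSE_CODONS, CodonAlignment

_N = len(SENSE_CODONS)


class _SiteTransitions:
    """log P(t) provider, either shared across sites or per-site."""

    def __init__(self, model: SubstitutionModel | None = None,
                 Q_stack: np.ndarray | None = None,
                 frequencies: np.ndarray | None = None, n_sites: int = 0):
        if model is not None:
            self.per_site = False
            self.model = model
            self.pi = model.frequencies
        else:
            self.per_site = True
            self.pi = np.asarray(frequencies, dtype=float)
            sqrt_pi = np.sqrt(np.maximum(self.pi, 1e-300))
            B = (sqrt_pi[None, :, None] * Q_stack) / sqrt_pi[None, None, :]
            B = (B + B.transpose(0, 2, 1)) / 2.0
            self.eigval, eigvec = np.linalg.eigh(B)
            self.right = eigvec / sqrt_pi[None, :, None]
            self.left = eigvec.transpose(0, 2, 1) * sqrt_pi[None, None, :]
        self.n_sites = n_sites

    def log_P(self, t: float) -> np.ndarray:
        """(sites, n, n) log transition matrices for branch length t."""
        if not self.per_site:
            P = self.model.transition_matrix(t)
            P = np.broadcast_to(P, (self.n_sites, _N, _N))
        else:
            expl = np.exp(self.eigval * t)
            P = np.matmul(self.right * expl[:, None, :], self.left)
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(P, 1e-300))


def collapsed_site_rate_matrices(fit) -> tuple[np.ndarray, np.ndarray]:
    """Per-site rate matrices from a REL fit, collapsing the class grid to its
    posterior-mean (dN, dS) at each site."""
    from ..rel.codon_model import codon_exchangeability_parts
    post = fit.site_posteriors_matrix               # (sites, 3, 3)
    dn_site = post.sum(axis=2) @ fit.grid.dn_values_raw
    ds_site = post.sum(axis=1) @ fit.grid.ds_values_raw
    syn, nonsyn = codon_exchangeability_parts(fit.nucleotide_mles)
    pi = fit.codon_frequencies
    syn = syn * pi[None, :] * fit.branch_scale
    nonsyn = nonsyn * pi[None, :] * fit.branch_scale
    Qs = dn_site[:, None, None] * nonsyn[None] + ds_site[:, None, None] * syn[None]
    idx = np.arange(_N)
    Qs[:, idx, idx] = -Qs.sum(axis=2)
    return Qs, pi


def joint_ancestral_codons(tree, codon_aln: CodonAlignment,
                           model: SubstitutionModel | None = None,
                           Q_stack: np.ndarray | None = None,
                           frequencies: np.ndarray | None = None,
                           scale: float = 1.0) -> dict:
    """Jointly most probable internal-node codons per site.

    Returns node -> int array (n_sites,) of sense-codon indices; leaves carry
    their observed codes (-1 for gap/ambiguous).
    """
    codes = encode_codon_leaf_codes(codon_aln)
    codes = {n: codes[n] for n in tree.leaf_names()}
    n_sites = codon_aln.n_codon_sites
    trans = _SiteTransitions(model=model, Q_stack=Q_stack,
                             frequencies=frequencies, n_sites=n_sites)

    up: dict[int, np.ndarray] = {}        # C_v(parent state): (sites, n)
    choice: dict[int, np.ndarray] = {}    # argmax child state: (sites, n)
    below: dict[int, np.ndarray] = {}     # sum over children of C_c at own state

    for node in tree.postorder():
        if node.is_leaf:
            obs = codes[node.name]
            logP = trans.log_P((node.length or 0.0) * scale)
            sites_idx = np.arange(n_sites)[:, None]
            states_idx = np.arange(_N)[None, :]
            C = logP[sites_idx, states_idx, np.clip(obs, 0, None)[:, None]]
            up[id(node)] = np.where(obs[:, None] >= 0, C, 0.0)
            continue
        tmp = np.zeros((n_sites, _N))
        for child in node.children:
            tmp += up.pop(id(child))
        below[id(node)] = tmp
        if node.parent is not None:
            logP = trans.log_P((node.length or 0.0) * scale)
            scores = logP + tmp[:, None, :]
            choice[id(node)] = scores.argmax(axis=2)
            up[id(node)] = scores.max(axis=2)

    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(trans.pi, 1e-300))
    root_total = log_pi[None, :] + below[id(tree.root)]
    assignment: dict = {tree.root: root_total.argmax(axis=1)}

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = assignment[node.parent]
        if node.is_leaf:
            assignment[node] = codes[node.name]
        else:
            assignment[node] = np.take_along_axis(
                choice[id(node)], parent_state[:, None], axis=1)[:, 0]
    return assignment
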