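"""Site x branch non-synonymous substitution indicator maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..seqio import CODON_TO_AA, SENSE_CODONS, CodonAlignment

_AA = [CODON_TO_AA[c] for c in SENSE_CODONS]


@dataclass
class SubstitutionMap:
    """Binary indicator: 1 iff an amino-acid-changing substitution was
    inferred on that branch at that site."""

    sites: list[int]                 # reference positions
    branches: list[str]
    matrix: np.ndarray               # (n_sites, n_branches), values in {0, 1}

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("substitution map must be binary")
        if self.matrix.shape != (len(self.sites), len(self.branches)):
            raise ValueError("matrix shape mismatch")

    @property
    def branch_count(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def _branch_label(node, index: int) -> str:
    return node.name if (node.is_leaf and node.name) else f"branch{index}"


def substitution_map(tree, codon_aln: CodonAlignment, reconstruction,
                     site_labels=None) -> SubstitutionMap:
    """Compare reconstructed parent/child codons along every branch; a branch
    scores 1 at a site when the translated amino acids differ.  Gap or
    ambiguous child states contribute 0 (conservative)."""
    n_sites = codon_aln.n_codon_sites
    if site_labels is None:
        offset = codon_aln.origin_offset // 3
        site_labels = [s + offset for s in range(1, n_sites + 1)]
    aa_index = np.array([ord(a) for a in _AA])

    cols = []
    labels = []
    for i, node in enumerate(tree.postorder()):
        if node.parent is None:
            continue
        child_states = np.asarray(reconstruction[node])
        parent_states = np.asarray(reconstruction[node.parent])
        ok = (child_states >= 0) & (parent_states >= 0)
        nonsyn = np.zeros(n_sites, dtype=np.int8)
        nonsyn[ok] = (aa_index[child_states[ok]]
                      != aa_index[parent_states[ok]]).astype(np.int8)
        cols.append(nonsyn)
        labels.append(_branch_label(node, i))
    return SubstitutionMap(sites=list(site_labels), branches=labels,
                           matrix=np.stack(cols, axis=1))


def filter_sites(smap: SubstitutionMap, min_count: int = 3) -> SubstitutionMap:
    """Retain sites with at least ``min_count`` non-synonymous branches."""
    keep = smap.branch_count >= min_count
    return SubstitutionMap(
        sites=[s for s, k in zip(smap.sites, keep) if k],
        branches=list(smap.branches),
        matrix=smap.matrix[keep],
    )
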