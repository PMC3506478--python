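"""61-state reversible codon models with separate synonymous/non-synonymous
rates, and codon-frequency estimators (F3x4 / F61)."""

from __future__ import annotations

import numpy as np

from ..seqio import CODON_TO_AA, SENSE_CODONS, CodonAlignment
from ..phylo.model import NUCLEOTIDES, SubstitutionModel

_N_CODONS = len(SENSE_CODONS)
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


def _single_change_tables():
    """For each ordered codon pair differing at one position: the nucleotide
    pair key and whether the change is synonymous."""
    pair_key = {}
    synonymous = {}
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            key = "".join(sorted((ci[p], cj[p])))
            pair_key[(i, j)] = key
            synonymous[(i, j)] = CODON_TO_AA[ci] == CODON_TO_AA[cj]
    return pair_key, synonymous

_PAIR_KEY, _IS_SYN = _single_change_tables()

#: boolean masks per nucleotide-pair key, split by synonymous / non-synonymous
_MASKS: dict[str, tuple[np.ndarray, np.ndarray]] = {}
for _key in ("AC", "AG", "AT", "CG", "CT", "GT"):
    syn = np.zeros((_N_CODONS, _N_CODONS), dtype=bool)
    nonsyn = np.zeros((_N_CODONS, _N_CODONS), dtype=bool)
    for (i, j), k in _PAIR_KEY.items():
        if k == _key:
            (syn if _IS_SYN[(i, j)] else nonsyn)[i, j] = True
    _MASKS[_key] = (syn, nonsyn)


def codon_exchangeability_parts(nuc_rates: dict[str, float]):
    """Synonymous and non-synonymous exchangeability templates: symmetric
    matrices carrying the nucleotide rate of the single-position change."""
    syn = np.zeros((_N_CODONS, _N_CODONS))
    nonsyn = np.zeros((_N_CODONS, _N_CODONS))
    for key, (ms, mn) in _MASKS.items():
        r = float(nuc_rates.get(key, 1.0))
        syn[ms] = r
        nonsyn[mn] = r
    return syn, nonsyn


def build_codon_model(nuc_rates: dict[str, float], codon_freqs, dn: float,
                      ds: float, normalize: bool = False) -> SubstitutionModel:
    """MG94/GY-style model: single-nucleotide changes get the nucleotide
    exchangeability times the target-codon frequency, scaled by ``ds`` when
    synonymous and ``dn`` when amino-acid changing.  Multi-nucleotide changes
    have rate exactly 0."""
    if dn < 0 or ds < 0:
        raise ValueError("dn and ds must be nonnegative")
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (_N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-6:
        raise ValueError("codon frequencies must be a probability vector over "
                         f"{_N_CODONS} sense codons")
    syn, nonsyn = codon_exchangeability_parts(nuc_rates)
    S = ds * syn + dn * nonsyn
    return SubstitutionModel(SENSE_CODONS, S, pi / pi.sum(), normalize=normalize)


_FREQ_FLOOR = 1e-8


def estimate_codon_frequencies(codon_aln: CodonAlignment,
                               method: str = "F3x4",
                               pseudocount: float = 0.5) -> np.ndarray:
    """Codon frequency vector over the 61 sense codons.

    F3x4: products of position-specific nucleotide frequencies, renormalized
    over sense codons.  F61: observed codon counts with a pseudocount.
    """
    rows = codon_aln.codon_rows()
    if method.upper() == "F61":
        counts = np.full(_N_CODONS, float(pseudocount))
        index = {c: i for i, c in enumerate(SENSE_CODONS)}
        for _, codons in rows:
            for c in codons:
                if c in index:
                    counts[index[c]] += 1
        if counts.sum() == 0:
            raise ValueError("empty codon alignment")
        return counts / counts.sum()
    if method.upper() != "F3X4":
        raise ValueError(f"unknown frequency method {method!r}")

    pos_counts = np.zeros((3, 4))
    for _, codons in rows:
        for c in codons:
            for p, nt in enumerate(c):
                if nt in _NT_INDEX:
                    pos_counts[p, _NT_INDEX[nt]] += 1
    if np.any(pos_counts.sum(axis=1) == 0):
        raise ValueError("empty codon alignment")
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array([pos_freq[0, _NT_INDEX[c[0]]]
                   * pos_freq[1, _NT_INDEX[c[1]]]
                   * pos_freq[2, _NT_INDEX[c[2]]] for c in SENSE_CODONS])
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()
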