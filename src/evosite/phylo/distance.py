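"""Pairwise maximum-likelihood distances under a reversible model."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .model import SubstitutionModel

D_MAX = 10.0


class SaturationWarning(UserWarning):
    pass


def _pair_counts(row_i: str, row_j: str, model: SubstitutionModel) -> np.ndarray:
    """State-pair count matrix over comparable (both non-missing) columns."""
    ci = model.encode(row_i)
    cj = model.encode(row_j)
    ok = (ci >= 0) & (cj >= 0)
    if not ok.any():
        raise ValueError("no comparable columns between sequences")
    n = model.n_states
    counts = np.zeros((n, n))
    np.add.at(counts, (ci[ok], cj[ok]), 1.0)
    return counts


def ml_distance(row_i: str, row_j: str, model: SubstitutionModel) -> float:
    """Branch length maximizing the 2-sequence likelihood, bracketed in
    [0, D_MAX].  Identical sequences give 0; saturated pairs cap at D_MAX."""
    if len(row_i) != len(row_j):
        raise ValueError("rows of unequal length")
    counts = _pair_counts(row_i, row_j, model)
    if counts.sum() == np.trace(counts):
        return 0.0
    log_pi = np.log(model.frequencies)

    def neg_loglik(t):
        P = model.transition_matrix(t)
        with np.errstate(divide="ignore"):
            logP = np.log(np.maximum(P, 1e-300))
        return -float((counts * (log_pi[:, None] + logP)).sum())

    res = minimize_scalar(neg_loglik, bounds=(1e-9, D_MAX), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    if d > 0.99 * D_MAX:
        warnings.warn("pairwise distance at saturation cap", SaturationWarning)
        return D_MAX
    return d


def distance_matrix(aln, model: SubstitutionModel) -> tuple[np.ndarray, list[str]]:
    """Symmetric ML distance matrix over all alignment rows."""
    ids = aln.identifiers
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_distance(aln.records[i][1],
                                            aln.records[j][1], model)
    return D, ids
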