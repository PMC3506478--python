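"""Reversible substitution models over arbitrary finite state spaces.

A model is defined by symmetric exchangeabilities and stationary frequencies;
the rate matrix is Q_ij = s_ij * pi_j (i != j), normalized to one expected
substitution per unit time.  Transition matrices are computed through the
symmetric eigendecomposition of diag(sqrt(pi)) Q diag(1/sqrt(pi)), which is
exact for this model class and cheap to reuse across branch lengths.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")
NUCLEOTIDES = tuple("ACGT")

#: unordered nucleotide pairs in canonical order; AG is the GTR reference rate
NUC_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


class SubstitutionModel:
    def __init__(self, state_space, exchangeabilities, frequencies,
                 normalize: bool = True):
        self.states = tuple(state_space)
        n = len(self.states)
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if S.shape != (n, n):
            raise ValueError("exchangeability matrix shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(S < 0) or np.any(pi < 0):
            raise ValueError("negative exchangeability or frequency")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        pi = pi / pi.sum()

        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if normalize:
            mu = -np.dot(pi, np.diag(Q))
            if mu <= 0:
                raise ValueError("degenerate rate matrix")
            Q /= mu
        self.exchangeabilities = S
        self.frequencies = pi
        self.Q = Q
        self.state_index = {s: i for i, s in enumerate(self.states)}
        self._decompose()

    def _decompose(self) -> None:
        pi = self.frequencies
        mask = pi > 0
        sqrt_pi = np.sqrt(np.where(mask, pi, 1.0))
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        # symmetrize to kill roundoff before eigh
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]          # V^T diag(sqrt pi)
        self._right = (eigvec.T / sqrt_pi[None, :]).T     # diag(1/sqrt pi) V

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"invalid branch length {t}")
        P = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts) -> np.ndarray:
        """Stacked P(t) for a vector of branch lengths, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        expl = np.exp(np.multiply.outer(ts, self._eigval))
        P = np.einsum("ij,tj,jk->tik", self._right, expl, self._left,
                      optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def encode(self, row: str) -> np.ndarray:
        """Integer state codes for a symbol string; -1 marks gap/ambiguity."""
        return np.array([self.state_index.get(s, -1) for s in row], dtype=np.int64)


def _load_tsv_matrix(name: str):
    import pandas as pd
    with resources.files("evosite.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


_JTT_CACHE: dict[str, SubstitutionModel] = {}


def jtt_model() -> SubstitutionModel:
    """JTT amino-acid model from the embedded data files (cached)."""
    if "jtt" not in _JTT_CACHE:
        S = _load_tsv_matrix("jtt_exchangeabilities.tsv")
        pi = _load_tsv_matrix("jtt_frequencies.tsv")["freq"]
        S = S.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(dtype=float)
        pi = pi.loc[list(AMINO_ACIDS)].to_numpy(dtype=float)
        _JTT_CACHE["jtt"] = SubstitutionModel(AMINO_ACIDS, S, pi / pi.sum())
    return _JTT_CACHE["jtt"]


def gtr_model(rates: dict[str, float], frequencies,
              normalize: bool = True) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``rates`` maps unordered pairs (e.g. "AC") to relative exchangeabilities;
    missing pairs default to 1 (the AG reference convention).
    """
    n = 4
    S = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(NUCLEOTIDES)}
    for pair in NUC_PAIRS:
        r = float(rates.get(pair, 1.0))
        i, j = idx[pair[0]], idx[pair[1]]
        S[i, j] = S[j, i] = r
    return SubstitutionModel(NUCLEOTIDES, S, frequencies, normalize=normalize)


def poisson_model(state_space) -> SubstitutionModel:
    """Equal-rates, equal-frequency model (testing and neutral fallbacks)."""
    n = len(state_space)
    S = np.ones((n, n)) - np.eye(n)
    return SubstitutionModel(state_space, S, np.full(n, 1.0 / n))
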