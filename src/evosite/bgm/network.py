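"""Co-evolution network inference over binary substitution maps.

Order-based MCMC: the chain walks over node orderings (Friedman-Koller
style); given an ordering, each node's parent set (in-degree <= 2) is
marginalized exactly over all candidates compatible with the order, so edge
posteriors are averages of exact per-order edge probabilities.  Family
scores are Beta(1,1)-integrated (K2-style) marginal likelihoods under a
modular prior: uniform over parent sets within each cardinality, with a
truncated-geometric prior on in-degree (decay configurable).  Plain
uniform-over-structures priors grossly overcall chance correlations at the
observation counts these maps have, hence the explicit sparsity control.

Edge posteriors are direction-marginalized; everything is deterministic
given (seed, chain_length, burn_in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .submap import SubstitutionMap

INDEGREE_DECAY = 0.1


@dataclass
class BgmNetwork:
    nodes: list[int]
    edge_posterior: dict[tuple[int, int], float]
    called_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    groups: list[frozenset] = field(default_factory=list)
    mcmc_diagnostics: dict = field(default_factory=dict)


def _family_scores(data: np.ndarray, max_parents: int, decay: float):
    """Candidate parent sets (shared list) and per-node log family scores.

    Returns (membership matrix over sets x nodes, score matrix nodes x sets);
    sets containing the child node score -inf.
    """
    n_obs, n = data.shape
    sets: list[tuple[int, ...]] = [()]
    for k in range(1, max_parents + 1):
        sets.extend(combinations(range(n), k))
    S = np.zeros((len(sets), n), dtype=bool)
    for si, pa in enumerate(sets):
        for p in pa:
            S[si, p] = True

    F = np.full((n, len(sets)), -np.inf)
    for j in range(n):
        x = data[:, j]
        for si, pa in enumerate(sets):
            if j in pa:
                continue
            if pa:
                config = np.zeros(n_obs, dtype=np.int64)
                for p in pa:
                    config = config * 2 + data[:, p]
            else:
                config = np.zeros(n_obs, dtype=np.int64)
            score = 0.0
            for c in range(2 ** len(pa)):
                mask = config == c
                n1 = int(x[mask].sum())
                n0 = int(mask.sum()) - n1
                score += (gammaln(n1 + 1) + gammaln(n0 + 1)
                          - gammaln(n0 + n1 + 2))
            score -= np.log(comb(n - 1, len(pa)))
            score += len(pa) * np.log(decay)
            F[j, si] = score
    return S, F


def _node_logweights(S, F, pos):
    """Per-node log marginal over parent sets valid for ordering ``pos``."""
    pred = pos[None, :] < pos[:, None]          # pred[j, k]: k precedes j
    violates = (S[None, :, :] & ~pred[:, None, :]).any(axis=2)
    Fm = np.where(violates, -np.inf, F)
    mx = Fm.max(axis=1)
    with np.errstate(invalid="ignore"):
        W = mx + np.log(np.exp(Fm - mx[:, None]).sum(axis=1))
    return W, Fm


def bgm_fit(smap: SubstitutionMap, max_parents: int = 2,
            chain_length: int = 100_000, burn_in: int = 10_000,
            seed: int = 0, thin: int = 10,
            indegree_decay: float = INDEGREE_DECAY) -> BgmNetwork:
    """Order-MCMC edge posteriors for a filtered substitution map."""
    n = len(smap.sites)
    if n < 2:
        raise ValueError("need at least 2 filtered sites")
    if burn_in >= chain_length:
        raise ValueError("burn_in must be smaller than chain_length")
    data = smap.matrix.T.astype(np.int64)        # observations x variables
    S, F = _family_scores(data, max_parents, indegree_decay)
    rng = np.random.default_rng(seed)

    pos = np.argsort(rng.permutation(n))
    W, _ = _node_logweights(S, F, pos)
    total = W.sum()

    post = np.zeros((n, n))
    n_samples = 0
    accepted = 0
    swaps = rng.integers(0, n, size=(chain_length, 2))
    log_u = np.log(rng.random(chain_length))

    for step in range(chain_length):
        a, b = swaps[step]
        if a != b:
            new_pos = pos.copy()
            new_pos[a], new_pos[b] = pos[b], pos[a]
            W_new, _ = _node_logweights(S, F, new_pos)
            if log_u[step] < W_new.sum() - total:
                pos, W = new_pos, W_new
                total = W.sum()
                accepted += 1
        if step >= burn_in and (step - burn_in) % thin == 0:
            W_cur, Fm = _node_logweights(S, F, pos)
            weights = np.exp(Fm - W_cur[:, None])
            post += (weights @ S).T              # post[i, j] += P(i->j | order)
            n_samples += 1

    post /= max(n_samples, 1)
    pair_post = post + post.T

    posterior = {}
    for i in range(n):
        for j in range(i + 1, n):
            posterior[(smap.sites[i], smap.sites[j])] = float(pair_post[i, j])

    network = BgmNetwork(
        nodes=list(smap.sites),
        edge_posterior=posterior,
        mcmc_diagnostics={
            "chain_length": chain_length, "burn_in": burn_in, "seed": seed,
            "thin": thin, "n_samples": n_samples,
            "indegree_decay": indegree_decay,
            "acceptance_rate": accepted / chain_length,
        },
    )
    pairs_called, groups = call_coevolving(network)
    network.called_pairs = pairs_called
    network.groups = groups
    return network


def call_coevolving(network: BgmNetwork, threshold: float = 0.5):
    """Pairs at or above the posterior threshold, plus connected-component
    groups of the undirected graph over called pairs."""
    called = [(a, b, p) for (a, b), p in sorted(network.edge_posterior.items())
              if p >= threshold]
    g = nx.Graph()
    for a, b, _ in called:
        g.add_edge(a, b)
    groups = sorted((frozenset(c) for c in nx.connected_components(g)),
                    key=lambda s: min(s))
    return called, groups
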