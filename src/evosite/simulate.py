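"""Seeded synthetic-data generators: Yule trees, gamma-rate protein
alignments, codon alignments with (dN, dS) site classes, and coupled
co-evolving site pairs.

Every generator is deterministic given its seed; truth tables are first-class
outputs so recovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bgm.submap import _branch_label
from .phylo.model import SubstitutionModel, jtt_model
from .phylo.tree import Node, PhyloTree
from .rel.codon_model import build_codon_model
from .seqio import (CODON_TO_AA, NUCLEOTIDE, PROTEIN, SENSE_CODONS,
                    CodonAlignment, MultipleAlignment)


@dataclass
class SimulationSpec:
    """Bundle of generator settings (see the individual simulate_* functions)."""
    seed: int
    n_taxa: int = 12
    depth: float = 1.0
    n_sites: int = 300
    alphabet: str = PROTEIN
    alpha: float = 1.0
    dn_values: tuple = (0.1, 1.0, 4.0)
    ds_values: tuple = (1.0, 1.0, 1.0)
    class_weights: object = None           # (3,3) matrix or None for uniform
    site_classes: object = None            # explicit (i, j) per site
    coupling_pairs: list = field(default_factory=list)  # (leader, follower, rho)
    nuc_rates: dict = field(default_factory=dict)
    tree: PhyloTree | None = None


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def star_tree(n_taxa: int, branch_length: float) -> PhyloTree:
    """Basal multifurcation with equal terminal branches.  Substitution
    events on such trees are branch-identifiable, which makes it the
    preferred shape for event-placement recovery audits."""
    root = Node()
    for i in range(n_taxa):
        root.add_child(Node(name=f"t{i + 1}", length=branch_length))
    return PhyloTree(root)


def simulate_tree(n_taxa: int, depth: float, seed: int) -> PhyloTree:
    """Yule-process topology; ultrametric, scaled so root-to-tip = depth."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active = [(a, 0.0), (b, 0.0)]      # (node, birth time)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node, birth = active.pop(k)
        node.length = t - birth
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / n_taxa)
    for i, (node, birth) in enumerate(active):
        node.length = t - birth
        node.name = f"t{i + 1}"
    tree = PhyloTree(root)
    scale = depth / t
    for node in tree.branches():
        node.length = (node.length or 0.0) * scale
    # name remaining internal leaves deterministically (already named above)
    leaf_id = 1
    for node in tree.postorder():
        if node.is_leaf and node.name is None:
            node.name = f"t{leaf_id}"
            leaf_id += 1
    return tree


def _sample_states(P_rows: np.ndarray, rng) -> np.ndarray:
    """Draw one state per row of a stack of probability vectors."""
    cdf = np.cumsum(P_rows, axis=1)
    u = rng.random(len(P_rows))
    return (u[:, None] < cdf).argmax(axis=1)


# ---------------------------------------------------------------------------
# protein
# ---------------------------------------------------------------------------

def simulate_protein(tree: PhyloTree, n_sites: int, alpha: float, seed: int,
                     model: SubstitutionModel | None = None):
    """JTT + gamma-rates protein alignment.

    Returns (MultipleAlignment, true per-site rates, substitution-count
    vector counting branches on which the state changed).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    model = model or jtt_model()
    rng = np.random.default_rng(seed)
    rates = rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_sites)

    states = {tree.root: _sample_states(
        np.tile(model.frequencies, (n_sites, 1)), rng)}
    change_counts = np.zeros(n_sites, dtype=int)
    for node in tree.preorder():
        if node is tree.root:
            continue
        t = node.length or 0.0
        P_all = model.transition_matrices(rates * t)       # (sites, n, n)
        parent = states[node.parent]
        rows = P_all[np.arange(n_sites), parent]
        child = _sample_states(rows, rng)
        change_counts += child != parent
        states[node] = child

    recs = [(leaf.name, "".join(model.states[s] for s in states[leaf]))
            for leaf in tree.leaves()]
    aln = MultipleAlignment(recs, PROTEIN)
    return aln, rates, change_counts


def simulate_protein_with_block(tree: PhyloTree, n_sites: int,
                                block_start: int, block_len: int,
                                rate_multiplier: float, seed: int,
                                model: SubstitutionModel | None = None):
    """Protein alignment with homogeneous rates except for a planted block of
    fast columns (1-based ``block_start``, length ``block_len``).

    Returns (alignment, true per-site rate vector).
    """
    model = model or jtt_model()
    rng = np.random.default_rng(seed)
    rates = np.ones(n_sites)
    rates[block_start - 1: block_start - 1 + block_len] = rate_multiplier
    states = {tree.root: _sample_states(
        np.tile(model.frequencies, (n_sites, 1)), rng)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P_all = model.transition_matrices(rates * (node.length or 0.0))
        parent = states[node.parent]
        states[node] = _sample_states(P_all[np.arange(n_sites), parent], rng)
    recs = [(leaf.name, "".join(model.states[s] for s in states[leaf]))
            for leaf in tree.leaves()]
    return MultipleAlignment(recs, PROTEIN), rates


# ---------------------------------------------------------------------------
# codons
# ---------------------------------------------------------------------------

def _codon_neighbors():
    """Per codon: list of (target index, synonymous?) single-nt neighbors."""
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    out = []
    for c in SENSE_CODONS:
        nb = []
        for p in range(3):
            for n in "ACGT":
                if n == c[p]:
                    continue
                t = c[:p] + n + c[p + 1:]
                if t in idx:
                    nb.append((idx[t], CODON_TO_AA[c] == CODON_TO_AA[t]))
        out.append(nb)
    return out

_NEIGHBORS = _codon_neighbors()


def _grid_models(dn_values, ds_values, nuc_rates, freqs):
    """Rate matrices for the 3x3 grid, sharing the neutral normalization so
    branch lengths mean neutral expected substitutions per codon site."""
    neutral = build_codon_model(nuc_rates, freqs, 1.0, 1.0, normalize=False)
    pi = neutral.frequencies
    mu = -float(pi @ np.diag(neutral.Q))
    models = {}
    for i, dn in enumerate(dn_values):
        for j, ds in enumerate(ds_values):
            m = build_codon_model(nuc_rates, freqs, dn / mu, ds / mu,
                                  normalize=False)
            models[(i, j)] = m
    return models, pi


def _default_codon_freqs():
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


def _assign_classes(spec: SimulationSpec, rng) -> list[tuple[int, int]]:
    if spec.site_classes is not None:
        classes = [tuple(c) for c in spec.site_classes]
        if len(classes) != spec.n_sites:
            raise ValueError("site_classes must cover all sites")
        return classes
    w = spec.class_weights
    if w is None:
        w = np.full((3, 3), 1.0 / 9)
    w = np.asarray(w, dtype=float).reshape(9)
    draw = rng.choice(9, size=spec.n_sites, p=w / w.sum())
    return [(d // 3, d % 3) for d in draw]


def _gillespie_site(tree, Q, pi, rng, root_state=None):
    """Event-level evolution of one site; returns leaf states and the list of
    (branch label, syn?) substitution events."""
    order = tree.postorder()
    labels = {id(n): _branch_label(n, i) for i, n in enumerate(order)}
    rates_out = -np.diag(Q)
    state = {id(tree.root): (int(_sample_states(pi[None, :], rng)[0])
                             if root_state is None else root_state)}
    events = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = state[id(node.parent)]
        t_left = node.length or 0.0
        while True:
            r = rates_out[s]
            if r <= 0:
                break
            dt = rng.exponential(1.0 / r)
            if dt > t_left:
                break
            t_left -= dt
            probs = np.maximum(Q[s], 0.0)
            probs[s] = 0.0
            probs = probs / probs.sum()
            new = int(_sample_states(probs[None, :], rng)[0])
            events.append((labels[id(node)],
                           CODON_TO_AA[SENSE_CODONS[s]] == CODON_TO_AA[SENSE_CODONS[new]]))
            s = new
        state[id(node)] = s
    leaf_states = {n.name: state[id(n)] for n in tree.leaves()}
    return leaf_states, events


def simulate_codons(tree: PhyloTree, spec: SimulationSpec):
    """Codon alignment with per-site (dN, dS) classes.

    Returns (CodonAlignment, truth DataFrame with per-site class values and a
    per-site count of amino-acid-changing events).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = _default_codon_freqs()
    models, pi = _grid_models(spec.dn_values, spec.ds_values,
                              spec.nuc_rates, freqs)
    classes = _assign_classes(spec, rng)

    leaf_names = tree.leaf_names()
    columns = {name: [] for name in leaf_names}
    truth_rows = []
    for s, (i, j) in enumerate(classes, start=1):
        Q = models[(i, j)].Q
        leaf_states, events = _gillespie_site(tree, Q, pi, rng)
        for name in leaf_names:
            columns[name].append(SENSE_CODONS[leaf_states[name]])
        n_nonsyn = sum(1 for _, syn in events if not syn)
        truth_rows.append({
            "site": s, "class_dn": i, "class_ds": j,
            "dn": spec.dn_values[i], "ds": spec.ds_values[j],
            "positive": spec.dn_values[i] > spec.ds_values[j],
            "n_nonsyn_events": n_nonsyn,
        })
    recs = [(name, "".join(columns[name])) for name in leaf_names]
    caln = CodonAlignment(MultipleAlignment(recs, NUCLEOTIDE))
    return caln, pd.DataFrame(truth_rows)


def simulate_coevolution(tree: PhyloTree, spec: SimulationSpec):
    """Codon alignment where follower sites repeat their leader's
    non-synonymous substitution branches with probability rho.

    Uncoupled sites evolve independently under their classes; followers evolve
    synonymously in the background and receive planted non-synonymous jumps.
    Returns (CodonAlignment, truth DataFrame with per-site role and the branch
    sets of planted non-synonymous events).
    """
    seen: set[int] = set()
    for leader, follower, rho in spec.coupling_pairs:
        if not (0.0 <= rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        for s in (leader, follower):
            if s in seen:
                raise ValueError(f"site {s} appears in more than one pair")
            seen.add(s)

    rng = np.random.default_rng(spec.seed)
    freqs = _default_codon_freqs()
    models, pi = _grid_models(spec.dn_values, spec.ds_values,
                              spec.nuc_rates, freqs)
    classes = _assign_classes(spec, rng)

    order = tree.postorder()
    branch_nodes = [n for n in order if n.parent is not None]
    branch_labels = {id(n): _branch_label(n, i) for i, n in enumerate(order)
                     if n.parent is not None}
    all_labels = [branch_labels[id(n)] for n in branch_nodes]

    followers = {f: (l, rho) for l, f, rho in spec.coupling_pairs}
    leaf_names = tree.leaf_names()
    columns = {name: {} for name in leaf_names}
    nonsyn_branches: dict[int, set] = {}
    truth_rows = []

    # independent sites (leaders included) first, recording leader events
    for s, (i, j) in enumerate(classes, start=1):
        if s in followers:
            continue
        Q = models[(i, j)].Q
        leaf_states, events = _gillespie_site(tree, Q, pi, rng)
        for name in leaf_names:
            columns[name][s] = SENSE_CODONS[leaf_states[name]]
        nonsyn_branches[s] = {b for b, syn in events if not syn}

    syn_model = build_codon_model(spec.nuc_rates or {}, freqs, 0.0, 1.0,
                                  normalize=False)
    for s, (i, j) in enumerate(classes, start=1):
        if s not in followers:
            continue
        leader, rho = followers[s]
        leader_branches = sorted(nonsyn_branches.get(leader, set()))
        planted = set()
        for b in leader_branches:
            if rng.random() < rho:
                planted.add(b)
            else:
                planted.add(all_labels[int(rng.integers(len(all_labels)))])
        # synonymous background + planted non-synonymous jumps
        state = {id(tree.root): int(_sample_states(pi[None, :], rng)[0])}
        for node in tree.preorder():
            if node is tree.root:
                continue
            cur = state[id(node.parent)]
            # synonymous drift along the branch
            t_left = node.length or 0.0
            Qs = syn_model.Q
            while True:
                r = -Qs[cur, cur]
                if r <= 0:
                    break
                dt = rng.exponential(1.0 / r)
                if dt > t_left:
                    break
                t_left -= dt
                probs = np.maximum(Qs[cur], 0.0)
                probs[cur] = 0.0
                cur = int(_sample_states((probs / probs.sum())[None, :], rng)[0])
            if branch_labels[id(node)] in planted:
                nonsyn = [t for t, syn in _NEIGHBORS[cur] if not syn]
                if nonsyn:
                    cur = int(nonsyn[int(rng.integers(len(nonsyn)))])
            state[id(node)] = cur
        for leaf in tree.leaves():
            columns[leaf.name][s] = SENSE_CODONS[state[id(leaf)]]
        nonsyn_branches[s] = planted

    for s, (i, j) in enumerate(classes, start=1):
        role = ("follower" if s in followers
                else "leader" if s in {l for l, _, _ in spec.coupling_pairs}
                else "independent")
        truth_rows.append({
            "site": s, "role": role,
            "partner": (followers[s][0] if role == "follower" else next(
                (f for l, f, _ in spec.coupling_pairs if l == s), None)),
            "rho": (followers[s][1] if role == "follower" else next(
                (r for l, _, r in spec.coupling_pairs if l == s), None)),
            "nonsyn_branches": ";".join(sorted(nonsyn_branches.get(s, set()))),
        })

    recs = [(name, "".join(columns[name][s] for s in range(1, spec.n_sites + 1)))
            for name in leaf_names]
    caln = CodonAlignment(MultipleAlignment(recs, NUCLEOTIDE))
    return caln, pd.DataFrame(truth_rows)
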