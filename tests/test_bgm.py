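import numpy as np
import pytest

from evosite.bgm import (SubstitutionMap, bgm_fit, call_coevolving,
                         filter_sites, joint_ancestral_codons,
                         substitution_map)
from evosite.bgm.network import BgmNetwork
from evosite.phylo.tree import Node, PhyloTree
from evosite.rel.codon_model import build_codon_model
from evosite.seqio import (CODON_TO_AA, SENSE_CODONS, CodonAlignment,
                           MultipleAlignment, NUCLEOTIDE)

NEUTRAL = build_codon_model({}, np.full(61, 1 / 61), 1.0, 1.0, normalize=True)


def star3(blen=0.1):
    root = Node()
    for n in "abc":
        root.add_child(Node(n, blen))
    return PhyloTree(root)


def caln_from_codons(rows):
    return CodonAlignment(MultipleAlignment(
        [(rid, "".join(codons)) for rid, codons in rows], NUCLEOTIDE))


class TestJointAncestral:
    def test_invariant_site(self):
        tree = star3()
        caln = caln_from_codons([("a", ["ATG"]), ("b", ["ATG"]), ("c", ["ATG"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        assert SENSE_CODONS[recon[tree.root][0]] == "ATG"

    def test_majority_root(self):
        tree = star3(0.05)
        caln = caln_from_codons([("a", ["AAA"]), ("b", ["AAA"]), ("c", ["AAG"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        assert SENSE_CODONS[recon[tree.root][0]] == "AAA"

    def test_brute_force_root_scan(self):
        # joint reconstruction beats every alternative root assignment on a star
        tree = star3(0.2)
        caln = caln_from_codons([("a", ["AAA"]), ("b", ["AAG"]), ("c", ["ATG"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        root_state = recon[tree.root][0]
        P = NEUTRAL.transition_matrix(0.2)
        obs = [SENSE_CODONS.index(c) for c in ("AAA", "AAG", "ATG")]

        def joint_prob(r):
            p = NEUTRAL.frequencies[r]
            for o in obs:
                p *= P[r, o]
            return p

        probs = [joint_prob(r) for r in range(61)]
        assert joint_prob(root_state) == pytest.approx(max(probs))

    def test_enumeration_oracle_two_internal(self):
        # ((a,b)u,(c,d)v) root w: maximize over (u, v, w) exhaustively
        root = Node()
        u = Node(length=0.1)
        v = Node(length=0.15)
        u.add_child(Node("a", 0.1))
        u.add_child(Node("b", 0.2))
        v.add_child(Node("c", 0.12))
        v.add_child(Node("d", 0.08))
        root.add_child(u)
        root.add_child(v)
        tree = PhyloTree(root)
        caln = caln_from_codons([("a", ["CTT"]), ("b", ["CTC"]),
                                 ("c", ["ATG"]), ("d", ["ATA"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)

        P = {t: NEUTRAL.transition_matrix(t) for t in (0.1, 0.2, 0.15, 0.12, 0.08)}
        obs = {k: SENSE_CODONS.index(c) for k, c in
               [("a", "CTT"), ("b", "CTC"), ("c", "ATG"), ("d", "ATA")]}
        best, best_p = None, -1
        for w in range(61):
            for uu in range(61):
                for vv in range(61):
                    p = (NEUTRAL.frequencies[w]
                         * P[0.1][w, uu] * P[0.15][w, vv]
                         * P[0.1][uu, obs["a"]] * P[0.2][uu, obs["b"]]
                         * P[0.12][vv, obs["c"]] * P[0.08][vv, obs["d"]])
                    if p > best_p:
                        best_p, best = p, (w, uu, vv)
        got = (recon[tree.root][0], recon[u][0], recon[v][0])
        assert got == best

    def test_deterministic(self):
        tree = star3(0.3)
        caln = caln_from_codons([("a", ["GGG"]), ("b", ["CCC"]), ("c", ["TTT"])])
        r1 = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        r2 = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        assert r1[tree.root][0] == r2[tree.root][0]


class TestSubstitutionMap:
    def test_identical_leaves_zero(self):
        tree = star3()
        caln = caln_from_codons([("a", ["ATG"]), ("b", ["ATG"]), ("c", ["ATG"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        smap = substitution_map(tree, caln, recon)
        assert smap.matrix.sum() == 0

    def test_single_nonsyn_leaf(self):
        tree = star3(0.05)
        # AAA/AAA/ACA: root AAA, one K->T change on branch c
        caln = caln_from_codons([("a", ["AAA"]), ("b", ["AAA"]), ("c", ["ACA"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        smap = substitution_map(tree, caln, recon)
        assert smap.matrix.sum() == 1
        ci = smap.branches.index("c")
        assert smap.matrix[0, ci] == 1

    def test_synonymous_only_zero_row(self):
        tree = star3(0.05)
        caln = caln_from_codons([("a", ["CTT"]), ("b", ["CTC"]), ("c", ["CTG"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        smap = substitution_map(tree, caln, recon)
        assert smap.matrix.sum() == 0

    def test_gap_child_contributes_zero(self):
        tree = star3(0.05)
        caln = caln_from_codons([("a", ["AAA"]), ("b", ["AAA"]), ("c", ["---"])])
        recon = joint_ancestral_codons(tree, caln, model=NEUTRAL)
        smap = substitution_map(tree, caln, recon)
        assert smap.matrix.sum() == 0


class TestFilterSites:
    def _map(self, row_sums):
        n_br = 8
        M = np.zeros((len(row_sums), n_br), dtype=np.int8)
        for i, k in enumerate(row_sums):
            M[i, :k] = 1
        return SubstitutionMap(sites=list(range(1, len(row_sums) + 1)),
                               branches=[f"b{i}" for i in range(n_br)],
                               matrix=M)

    def test_example(self):
        f = filter_sites(self._map([0, 2, 3, 5]), 3)
        assert f.sites == [3, 4]

    def test_min_zero_identity(self):
        smap = self._map([0, 2, 3])
        f = filter_sites(smap, 0)
        assert f.sites == smap.sites

    def test_boundary_inclusive(self):
        f = filter_sites(self._map([3]), 3)
        assert f.sites == [1]

    def test_idempotent(self):
        smap = self._map([1, 3, 4, 2])
        once = filter_sites(smap, 3)
        twice = filter_sites(once, 3)
        assert twice.sites == once.sites
        assert np.array_equal(twice.matrix, once.matrix)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionMap(sites=[1], branches=["b"], matrix=np.array([[2]]))


class TestBgmFit:
    def test_planted_identical_columns(self):
        rng = np.random.default_rng(0)
        M = rng.binomial(1, 0.4, size=(6, 20)).astype(np.int8)
        M[1] = M[0]
        smap = SubstitutionMap(sites=list(range(1, 7)),
                               branches=[f"b{i}" for i in range(20)], matrix=M)
        net = bgm_fit(smap, chain_length=30000, burn_in=3000, seed=1)
        assert net.edge_posterior[(1, 2)] >= 0.9

    def test_reproducible_bit_for_bit(self):
        rng = np.random.default_rng(5)
        M = rng.binomial(1, 0.3, size=(5, 15)).astype(np.int8)
        smap = SubstitutionMap(sites=list(range(1, 6)),
                               branches=[f"b{i}" for i in range(15)], matrix=M)
        n1 = bgm_fit(smap, chain_length=20000, burn_in=2000, seed=9)
        n2 = bgm_fit(smap, chain_length=20000, burn_in=2000, seed=9)
        assert n1.edge_posterior == n2.edge_posterior

    def test_single_site_error(self):
        smap = SubstitutionMap(sites=[1], branches=["b0", "b1"],
                               matrix=np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(ValueError, match="at least 2"):
            bgm_fit(smap, chain_length=100, burn_in=10, seed=0)

    def test_posteriors_in_unit_interval(self):
        rng = np.random.default_rng(8)
        M = rng.binomial(1, 0.3, size=(6, 12)).astype(np.int8)
        smap = SubstitutionMap(sites=list(range(1, 7)),
                               branches=[f"b{i}" for i in range(12)], matrix=M)
        net = bgm_fit(smap, chain_length=10000, burn_in=1000, seed=3)
        vals = np.array(list(net.edge_posterior.values()))
        assert np.all((vals >= 0) & (vals <= 1))


class TestCallCoevolving:
    def test_published_pair_grouping(self):
        # five pairs collapse into four connected components
        pairs = {(142, 144): 0.85, (152, 200): 0.59, (188, 200): 0.55,
                 (199, 325): 0.58, (203, 310): 0.68}
        net = BgmNetwork(nodes=sorted({x for p in pairs for x in p}),
                         edge_posterior=pairs)
        called, groups = call_coevolving(net, 0.5)
        assert len(called) == 5
        assert len(groups) == 4
        assert frozenset({142, 144}) in groups
        assert frozenset({152, 188, 200}) in groups
        assert frozenset({199, 325}) in groups
        assert frozenset({203, 310}) in groups

    def test_empty(self):
        net = BgmNetwork(nodes=[1, 2], edge_posterior={(1, 2): 0.2})
        called, groups = call_coevolving(net, 0.5)
        assert called == [] and groups == []

    def test_chain_single_group(self):
        net = BgmNetwork(nodes=[1, 2, 3, 4],
                         edge_posterior={(1, 2): 0.9, (2, 3): 0.8, (3, 4): 0.7})
        _, groups = call_coevolving(net, 0.5)
        assert groups == [frozenset({1, 2, 3, 4})]

    def test_threshold_boundary(self):
        net = BgmNetwork(nodes=[1, 2], edge_posterior={(1, 2): 0.5})
        called, _ = call_coevolving(net, 0.5)
        assert called == [(1, 2, 0.5)]
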