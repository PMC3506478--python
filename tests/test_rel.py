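import math

import numpy as np
import pytest

from evosite.rel import (CHIJ, DNAN, EQUAL_RATES, RECA, NucleotideConstraintSet,
                         bayes_factor_positive, build_codon_model,
                         classify_sites, estimate_codon_frequencies, fit_rel)
from evosite.rel.codon_model import codon_exchangeability_parts
from evosite.rel.fit import RateClassGrid, RelFit, _em_weights, \
    _CodonMixtureLikelihood, posterior_positive
from evosite.seqio import (CODON_TO_AA, SENSE_CODONS, CodonAlignment,
                           MultipleAlignment, NUCLEOTIDE)
from evosite.simulate import SimulationSpec, simulate_codons, simulate_tree


class TestConstraintSets:
    def test_chij_two_free_parameters(self):
        assert CHIJ.free_parameters() == ["R_AC", "R_AT"]
        rates = CHIJ.rates({"R_AC": 2.0, "R_AT": 3.0})
        assert rates["CT"] == 2.0      # CT tied to AC
        assert rates["GT"] == 3.0      # GT tied to AT
        assert rates["CG"] == 1.0      # CG tied to reference
        assert rates["AG"] == 1.0

    def test_reca_three_free(self):
        assert RECA.free_parameters() == ["R_CG", "R_CT", "R_GT"]
        rates = RECA.rates({"R_CG": 2, "R_CT": 3, "R_GT": 4})
        assert rates["AC"] == 1.0 and rates["AT"] == 1.0

    def test_dnan_ct_is_free(self):
        assert "R_CT" in DNAN.free_parameters()
        assert DNAN.rates({"R_CG": 2, "R_CT": 5})["GT"] == 1.0

    def test_bad_slots(self):
        with pytest.raises(ValueError):
            NucleotideConstraintSet("x", {"AC": "ref"})


class TestCodonModel:
    def test_multi_nucleotide_changes_zero(self):
        m = build_codon_model({}, np.full(61, 1 / 61), 1.0, 1.0)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert m.Q[i, j] == 0.0

    def test_dn_zero_kills_nonsynonymous(self):
        m = build_codon_model({}, np.full(61, 1 / 61), 0.0, 1.0)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i != j and CODON_TO_AA[ci] != CODON_TO_AA[cj]:
                    assert m.Q[i, j] == 0.0

    def test_neutral_scaling_identical(self):
        syn, nonsyn = codon_exchangeability_parts({"CT": 2.5})
        m = build_codon_model({"CT": 2.5}, np.full(61, 1 / 61), 1.0, 1.0)
        # at dn == ds the per-event scaling of syn and nonsyn changes is equal
        expected = (syn + nonsyn) / 61
        offdiag = m.Q - np.diag(np.diag(m.Q))
        assert np.allclose(offdiag, expected)

    def test_rows_sum_zero(self):
        m = build_codon_model({"AC": 0.5}, np.full(61, 1 / 61), 2.0, 0.7)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-10


class TestCodonFrequencies:
    def _aln(self, rows):
        return CodonAlignment(MultipleAlignment(rows, NUCLEOTIDE))

    def test_f61_single_codon(self):
        caln = self._aln([("a", "ATGATG"), ("b", "ATGATG")])
        freqs = estimate_codon_frequencies(caln, "F61", pseudocount=0.0)
        idx = SENSE_CODONS.index("ATG")
        assert freqs[idx] == pytest.approx(1.0)

    def test_f3x4_uniform(self):
        rows = []
        # cover all 4 nucleotides evenly at every codon position
        codons = ["ACG", "CGT", "GTA", "TAC"]
        seq = "".join(codons)
        rows = [("a", seq), ("b", seq[3:] + seq[:3])]
        freqs = estimate_codon_frequencies(self._aln(rows), "F3x4")
        assert freqs.sum() == pytest.approx(1.0)
        assert np.allclose(freqs, 1 / 61, atol=1e-9)

    def test_f3x4_sums_to_one(self):
        tree = simulate_tree(5, 0.5, seed=70)
        caln, _ = simulate_codons(tree, SimulationSpec(seed=71, n_sites=40))
        freqs = estimate_codon_frequencies(caln, "F3x4")
        assert freqs.sum() == pytest.approx(1.0)


class TestEmWeights:
    def test_mixture_identity(self):
        rng = np.random.default_rng(1)
        logL = rng.normal(size=(50, 9))
        counts = np.ones(50)
        w, ll, post = _em_weights(logL, counts)
        direct = np.log(np.exp(logL) @ w).sum()
        assert ll == pytest.approx(direct, rel=1e-9)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_single_class_dominates(self):
        logL = np.zeros((20, 9))
        logL[:, 4] = 8.0       # cell (dn_2, ds_2): representable as a product
        w, ll, post = _em_weights(logL, np.ones(20))
        assert w[4] > 0.99

    def test_weights_are_product_form(self):
        rng = np.random.default_rng(3)
        logL = rng.normal(size=(40, 9))
        w, _, _ = _em_weights(logL, np.ones(40))
        cell = w.reshape(3, 3)
        outer = np.outer(cell.sum(axis=1), cell.sum(axis=0))
        assert np.allclose(cell, outer, atol=1e-9)


@pytest.fixture(scope="module")
def small_fit():
    tree = simulate_tree(8, 0.9, seed=80)
    w = np.zeros((3, 3))
    w[0, 0], w[1, 0], w[2, 0] = 0.5, 0.4, 0.1
    spec = SimulationSpec(seed=81, n_sites=120, dn_values=(0.2, 0.7, 3.5),
                          ds_values=(1.0, 1.0, 1.0), class_weights=w)
    caln, truth = simulate_codons(tree, spec)
    fit = fit_rel(caln, tree, EQUAL_RATES, n_starts=2, maxfev=150,
                  nuc_rounds=1)
    return caln, tree, truth, fit


class TestFitRel:
    def test_posteriors_sum_to_one(self, small_fit):
        _, _, _, fit = small_fit
        sums = fit.site_posteriors_matrix.reshape(-1, 9).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_weights_valid(self, small_fit):
        _, _, _, fit = small_fit
        assert fit.grid.weights.min() >= 0
        assert fit.grid.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reported_ds_mean_one(self, small_fit):
        _, _, _, fit = small_fit
        ds_marg = fit.grid.weights.sum(axis=0)
        assert ds_marg @ fit.grid.ds_values == pytest.approx(1.0, rel=1e-6)

    def test_loglik_matches_independent_recompute(self, small_fit):
        # mixture log-likelihood == sum_sites log sum_classes w * L(site|class)
        # with L recomputed through the public codon-model + pruning route
        from evosite.phylo import site_log_likelihoods
        caln, _, _, fit = small_fit
        per_class = []
        for i in range(3):
            for j in range(3):
                m = build_codon_model(fit.nucleotide_mles,
                                      fit.codon_frequencies,
                                      fit.grid.dn_values[i],
                                      fit.grid.ds_values[j])
                ll = site_log_likelihoods(fit.tree, caln, m,
                                          rate=fit.branch_scale)
                per_class.append(ll)
        logL = np.stack(per_class, axis=1)          # (sites, 9)
        w = fit.grid.weights.reshape(9)
        mx = logL.max(axis=1)
        total = (mx + np.log(np.exp(logL - mx[:, None]) @ w)).sum()
        assert total == pytest.approx(fit.log_likelihood, abs=0.5)

    def test_site_posteriors_brute_force(self, small_fit):
        from evosite.phylo import site_log_likelihoods
        caln, _, _, fit = small_fit
        per_class = []
        for i in range(3):
            for j in range(3):
                m = build_codon_model(fit.nucleotide_mles,
                                      fit.codon_frequencies,
                                      fit.grid.dn_values[i],
                                      fit.grid.ds_values[j])
                per_class.append(site_log_likelihoods(fit.tree, caln, m,
                                                      rate=fit.branch_scale))
        logL = np.stack(per_class, axis=1)
        w = fit.grid.weights.reshape(9)
        a = logL + np.log(np.maximum(w, 1e-300))
        a -= a.max(axis=1, keepdims=True)
        post = np.exp(a)
        post /= post.sum(axis=1, keepdims=True)
        got = fit.site_posteriors_matrix.reshape(-1, 9)
        assert np.abs(got - post).max() < 2e-3

    def test_nesting_one_class(self, small_fit):
        # 3x3 mixture likelihood >= best single-class likelihood
        from evosite.phylo import site_log_likelihoods
        caln, _, _, fit = small_fit
        best = -math.inf
        for i in range(3):
            for j in range(3):
                m = build_codon_model(fit.nucleotide_mles,
                                      fit.codon_frequencies,
                                      fit.grid.dn_values[i],
                                      fit.grid.ds_values[j])
                ll = site_log_likelihoods(fit.tree, caln, m,
                                          rate=fit.branch_scale).sum()
                best = max(best, ll)
        assert fit.log_likelihood >= best - 1e-6


class TestBayesFactors:
    def _make_fit(self, prior, posts):
        grid = RateClassGrid(dn_values=np.array([0.1, 1.0, 4.0]),
                             ds_values=np.array([1.0, 1.0, 1.0]),
                             weights=np.array([[0.0, 0.45, 0.0],
                                               [0.0, 0.45, 0.0],
                                               [0.0, prior, 0.0]]),
                             dn_values_raw=np.array([0.1, 1.0, 4.0]),
                             ds_values_raw=np.ones(3))
        n = len(posts)
        mats = np.zeros((n, 3, 3))
        for k, p in enumerate(posts):
            mats[k, 2, 1] = p                    # positive class (dn=4, ds=1)
            mats[k, 0, 1] = (1 - p) / 2
            mats[k, 1, 1] = (1 - p) / 2
        fit = RelFit(grid=grid, nucleotide_mles={}, codon_frequencies=None,
                     branch_scale=1.0, log_likelihood=0.0, tree=None,
                     constraints=EQUAL_RATES, site_posteriors_matrix=mats,
                     site_labels=list(range(1, n + 1)))
        fit.prior_positive = float(grid.weights[grid.positive_mask].sum())
        return fit

    def test_closed_form(self):
        fit = self._make_fit(prior=0.1, posts=[0.5])
        assert bayes_factor_positive(fit, 1) == pytest.approx(9.0)

    def test_no_evidence_bf_one(self):
        fit = self._make_fit(prior=0.2, posts=[0.2])
        assert bayes_factor_positive(fit, 1) == pytest.approx(1.0)

    def test_posterior_one_infinite(self):
        fit = self._make_fit(prior=0.3, posts=[1.0])
        assert math.isinf(bayes_factor_positive(fit, 1))

    def test_degenerate_prior_nan(self):
        fit = self._make_fit(prior=0.0, posts=[0.5])
        fit.prior_positive = 0.0
        assert math.isnan(bayes_factor_positive(fit, 1))
        cats = classify_sites(fit)
        assert cats[0].category == "none"

    def test_single_class_posterior_one(self):
        # one class with weight 1 -> posterior 1 for that class everywhere
        logL = np.zeros((10, 9))
        w = np.zeros(9)
        w[4] = 1.0
        a = logL + np.log(np.maximum(w, 1e-300))
        a -= a.max(axis=1, keepdims=True)
        p = np.exp(a)
        p /= p.sum(axis=1, keepdims=True)
        assert np.allclose(p[:, 4], 1.0)


class TestClassification:
    def _fit_with_bfs(self, bfs, prior=0.1):
        # nudge posteriors up by an epsilon so inverse-mapped BFs do not fall
        # below the intended value through rounding
        posts = [prior * bf / (1 - prior + prior * bf) * (1 + 1e-12)
                 for bf in bfs]
        helper = TestBayesFactors()
        fit = helper._make_fit(prior=prior, posts=posts)
        return fit

    def test_thresholds(self):
        fit = self._fit_with_bfs([197.0, 49.9, 50.0, 9.99, 0.5])
        cats = [s.category for s in classify_sites(fit)]
        assert cats[0] == "strong"
        assert cats[1] == "weak"
        assert cats[2] == "strong"     # boundary: >= 50
        assert cats[3] == "none"
        assert cats[4] == "negative"

    def test_bf_values_round_trip(self):
        fit = self._fit_with_bfs([25.0])
        assert classify_sites(fit)[0].bayes_factor == pytest.approx(25.0)
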