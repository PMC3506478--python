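"""Random-effects-likelihood fit: 3 dN x 3 dS discrete rate classes, per-site
empirical-Bayes posteriors, Bayes factors and selection categories.

Two stages: (1) branch lengths and constrained exchangeabilities under the
nucleotide model; (2) relative branch lengths fixed, class values/weights and
a global branch scale maximize the mixture likelihood over codon sites.  The
dN and dS class distributions are independent (cell weight = product of
marginal weights), which is both the method's model and a guard against
isolating degenerate single cells on uninformative data.
The scale redundancy between class values and the branch scale is removed by
anchoring the middle dS value at 1 during optimization; reported grids are
renormalized so the weight-averaged dS equals 1 (raw fitted values are kept
alongside).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..phylo.likelihood import (compress_patterns, encode_codon_leaf_codes,
                                encode_leaf_codes)
from ..phylo.brlen import optimize_branch_lengths
from ..phylo.model import SubstitutionModel, gtr_model
from ..seqio import SENSE_CODONS, CodonAlignment
from .codon_model import codon_exchangeability_parts, estimate_codon_frequencies
from .constraints import NucleotideConstraintSet

_N = len(SENSE_CODONS)

STRONG_BF = 50.0
WEAK_BF = 10.0

#: classes count as positively selected only when dN exceeds dS by more than
#: the grid optimizer's resolution; otherwise "dN > dS" on a degenerate
#: (all-neutral) fit is a machine-precision coin flip and the prior/posterior
#: odds ratio is numerically meaningless.
POSITIVE_RATIO_TOL = 0.01


@dataclass
class RateClassGrid:
    dn_values: np.ndarray          # (3,)
    ds_values: np.ndarray          # (3,)
    weights: np.ndarray            # (3, 3); weights[i, j] = P(dn_i, ds_j)
    dn_values_raw: np.ndarray = None
    ds_values_raw: np.ndarray = None

    @property
    def ratios(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.ds_values[None, :] > 0,
                            self.dn_values[:, None] / self.ds_values[None, :],
                            np.inf)

    @property
    def positive_mask(self) -> np.ndarray:
        return self.dn_values[:, None] > (
            self.ds_values[None, :] * (1.0 + POSITIVE_RATIO_TOL))

    #: classes lighter than this carry fewer than ~1 site in a typical
    #: alignment and are not reported as selection regimes
    WEIGHT_FLOOR = 1e-3

    def positive_class_ratios(self) -> list[float]:
        """dN/dS of classes with dN > dS and non-trivial weight."""
        out = []
        for i in range(3):
            for j in range(3):
                if self.positive_mask[i, j] and self.weights[i, j] > self.WEIGHT_FLOOR:
                    out.append(float(self.ratios[i, j]))
        return out

    def main_positive_ratio(self) -> float | None:
        """Largest dN/dS among positively selected classes with non-trivial
        weight (None if no such class): the regime a planted or real
        positive class is fitted into."""
        ratios = self.positive_class_ratios()
        return max(ratios) if ratios else None


@dataclass
class SiteSelection:
    site: int
    posterior_positive: float
    bayes_factor: float
    category: str


#: extra free parameters of the 3x3 mixture over the homogeneous model
#: (2 extra dN + 2 extra dS values + 4 weight dof + 1, conservatively 9);
#: site-level positive-selection calls require the mixture to beat the
#: homogeneous fit by more than this AIC margin.  Without the gate,
#: near-flat neutral likelihood surfaces leave arbitrary low-weight
#: "positive" classes whose site Bayes factors are spurious.
HETEROGENEITY_GATE = 9.0


@dataclass
class RelFit:
    grid: RateClassGrid
    nucleotide_mles: dict[str, float]
    codon_frequencies: np.ndarray
    branch_scale: float
    log_likelihood: float
    tree: object
    constraints: NucleotideConstraintSet
    site_posteriors_matrix: np.ndarray = field(repr=False)  # (sites, 3, 3)
    prior_positive: float = 0.0
    per_site: list[SiteSelection] = field(default_factory=list)
    converged: bool = True
    start_log: list = field(default_factory=list)
    site_labels: list[int] = field(default_factory=list)
    heterogeneity_gain: float = math.inf
    selection_gate_passed: bool = True


# ---------------------------------------------------------------------------
# stage 1: nucleotide model
# ---------------------------------------------------------------------------

def empirical_nucleotide_frequencies(nuc_aln) -> np.ndarray:
    counts = np.zeros(4)
    order = "ACGT"
    for _, row in nuc_aln.records:
        for i, nt in enumerate(order):
            counts[i] += row.count(nt)
    if counts.sum() == 0:
        raise ValueError("no nucleotide data")
    return counts / counts.sum()


def fit_nucleotide(nuc_aln, tree, constraints: NucleotideConstraintSet,
                   rounds: int = 2):
    """Fit branch lengths and constrained GTR exchangeabilities by ML."""
    pi = empirical_nucleotide_frequencies(nuc_aln)
    free = constraints.free_parameters()
    values = {p: 1.0 for p in free}
    fitted = tree.copy()
    loglik = -math.inf
    for _ in range(rounds):
        model = gtr_model(constraints.rates(values), pi)
        fitted = optimize_branch_lengths(fitted, nuc_aln, model,
                                         tol=1e-3, max_sweeps=5, xatol=1e-4)
        if free:
            codes, wts, _ = compress_patterns(
                {n: model.encode(nuc_aln.row(n)) for n in fitted.leaf_names()})

            def neg(logv):
                vals = dict(zip(free, np.exp(logv)))
                m = gtr_model(constraints.rates(vals), pi)
                from ..phylo.likelihood import prune_site_loglik
                return -float(prune_site_loglik(fitted, codes, m) @ wts)

            res = minimize(neg, np.log([values[p] for p in free]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6, "maxfev": 400})
            values = dict(zip(free, np.exp(res.x)))
            loglik = -res.fun
        else:
            from ..phylo.likelihood import prune_site_loglik
            codes, wts, _ = compress_patterns(
                {n: model.encode(nuc_aln.row(n)) for n in fitted.leaf_names()})
            loglik = float(prune_site_loglik(fitted, codes, model) @ wts)
    return values, fitted, loglik, pi


# ---------------------------------------------------------------------------
# stage 2: codon mixture
# ---------------------------------------------------------------------------

class _CodonMixtureLikelihood:
    """Per-class per-site-pattern codon log-likelihoods on a fixed tree.

    Partial-likelihood matmuls run in ``dtype`` (float32 by default: per-node
    rescaling keeps partials well-conditioned and log accumulation stays in
    float64, so the loss is ~1e-6 relative — well inside optimizer tolerance).
    """

    def __init__(self, tree, codon_aln: CodonAlignment, nuc_rates, pi_codon,
                 dtype=np.float32):
        self.tree = tree
        codes = encode_codon_leaf_codes(codon_aln)
        codes = {n: codes[n] for n in tree.leaf_names()}
        self.codes, self.counts, self.inverse = compress_patterns(codes)
        self.n_patterns = len(self.counts)
        self.pi = np.asarray(pi_codon, dtype=float)
        syn, nonsyn = codon_exchangeability_parts(nuc_rates)
        self.syn_part = syn * self.pi[None, :]
        self.nonsyn_part = nonsyn * self.pi[None, :]
        self.sqrt_pi = np.sqrt(self.pi)
        self._order = tree.postorder()
        self._lengths = {id(n): (n.length or 0.0) for n in self._order}
        self.dtype = dtype

    def class_logliks(self, dn_vec, ds_vec, scale) -> np.ndarray:
        """(n_patterns, n_classes) log-likelihoods; classes ordered as the
        flattened (dn_i, ds_j) grid."""
        pairs = [(dn, ds) for dn in dn_vec for ds in ds_vec]
        C = len(pairs)
        Qs = np.empty((C, _N, _N))
        for c, (dn, ds) in enumerate(pairs):
            Q = dn * self.nonsyn_part + ds * self.syn_part
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            Qs[c] = Q
        B = (self.sqrt_pi[None, :, None] * Qs) / self.sqrt_pi[None, None, :]
        B = (B + B.transpose(0, 2, 1)) / 2.0
        eigval, eigvec = np.linalg.eigh(B)
        right = eigvec / self.sqrt_pi[None, :, None]
        left = eigvec.transpose(0, 2, 1) * self.sqrt_pi[None, None, :]

        dtype = self.dtype
        eye = np.eye(_N, dtype=dtype)
        partial: dict[int, np.ndarray] = {}
        log_scaler = np.zeros((C, self.n_patterns))
        for node in self._order:
            if node.is_leaf:
                codes = self.codes[node.name]
                L0 = np.where(codes[:, None] >= 0,
                              eye[np.clip(codes, 0, None)], 1.0).astype(dtype)
                L = np.broadcast_to(L0, (C, self.n_patterns, _N)).copy()
            else:
                L = np.ones((C, self.n_patterns, _N), dtype=dtype)
                for child in node.children:
                    t = self._lengths[id(child)] * scale
                    expl = np.exp(eigval * t)          # (C, 61)
                    P = np.matmul(right * expl[:, None, :], left)
                    np.clip(P, 0.0, None, out=P)
                    P /= P.sum(axis=2, keepdims=True)
                    L = L * np.matmul(partial.pop(id(child)),
                                      P.astype(dtype).transpose(0, 2, 1))
                mx = L.max(axis=2).astype(np.float64)
                safe = np.where(mx > 0, mx, 1.0).astype(dtype)
                L = L / safe[:, :, None]
                with np.errstate(divide="ignore"):
                    log_scaler += np.log(mx)
            partial[id(node)] = L
        lik = partial[id(self.tree.root)].astype(np.float64) @ self.pi
        with np.errstate(divide="ignore"):
            return (np.log(lik) + log_scaler).T   # (patterns, classes)


def _em_weights(logL, counts, w0=None, max_iter=500, tol=1e-9):
    """Maximize sum_p m_p log(sum_ij u_i v_j L_p,ij) over product weights.

    The dN and dS class distributions are independent (3 marginal weights
    each, cell weight = u_i * v_j).  The product structure is the cited
    method's model and it is an important regularizer: with 9 free cell
    weights the optimizer can isolate razor-thin cells (e.g. a near-zero-
    rate class with an arbitrary dN/dS) whose prior/posterior odds are
    numerically meaningless.
    """
    P, C = logL.shape
    k = int(round(math.sqrt(C)))
    assert k * k == C
    if w0 is None:
        u = np.full(k, 1.0 / k)
        v = np.full(k, 1.0 / k)
    else:
        # floor the warm start so classes zeroed at one optimizer point can
        # revive when the grid values move (EM zeros are absorbing)
        cell = np.asarray(w0, float).reshape(k, k)
        u = np.maximum(cell.sum(axis=1), 1e-6)
        v = np.maximum(cell.sum(axis=0), 1e-6)
        u /= u.sum()
        v /= v.sum()
    total = counts.sum()
    ll_old = -np.inf
    for _ in range(max_iter):
        w = np.outer(u, v).reshape(C)
        a = logL + np.log(np.maximum(w, 1e-300))[None, :]
        mx = a.max(axis=1)
        e = np.exp(a - mx[:, None])
        s = e.sum(axis=1)
        ll = float(counts @ (mx + np.log(s)))
        post = e / s[:, None]
        marg = (counts[:, None] * post).sum(axis=0).reshape(k, k) / total
        # weights may go to exact zero: a dead class must carry prior 0, or
        # its posterior/prior odds at favourable sites are pure noise
        u = marg.sum(axis=1)
        v = marg.sum(axis=0)
        u = u / u.sum() if u.sum() > 0 else np.full(k, 1.0 / k)
        v = v / v.sum() if v.sum() > 0 else np.full(k, 1.0 / k)
        if ll - ll_old < tol:
            break
        ll_old = ll
    # EM approaches boundary zeros only geometrically; classes below this
    # floor are dead and must carry exactly zero prior (their posterior/prior
    # odds at favourable sites would otherwise be numerically meaningless)
    u = np.where(u < 1e-5, 0.0, u)
    v = np.where(v < 1e-5, 0.0, v)
    u /= u.sum()
    v /= v.sum()
    # report the likelihood and posteriors of the final weights
    w = np.outer(u, v).reshape(C)
    a = logL + np.log(np.maximum(w, 1e-300))[None, :]
    mx = a.max(axis=1)
    e = np.exp(a - mx[:, None])
    s = e.sum(axis=1)
    ll = float(counts @ (mx + np.log(s)))
    post = e / s[:, None]
    return w, ll, post


_STARTS = (
    # dn multipliers (scaled by the 1-class omega estimate) and (ds_low,
    # ds_high); the middle dS is anchored at 1 during optimization
    ((0.5, 1.0, 2.0), (0.5, 2.0)),        # neutral-ish spread
    ((0.1, 0.5, 1.0), (0.5, 2.0)),        # purifying-heavy
    ((0.25, 1.0, 5.0), (0.5, 2.0)),       # positive-heavy
    ((0.1, 1.0, 3.0), (0.3, 3.0)),        # mixed wide
    ((0.3, 0.8, 1.5), (0.8, 1.3)),        # mixed narrow dS
)


def _stage2_init(engine):
    """Cheap 1-class pre-fits: global branch scale, then global omega."""
    from scipy.optimize import minimize_scalar
    one = np.ones(1)

    def neg_scale(log_s):
        L = engine.class_logliks(one, one, math.exp(log_s))
        return -float(engine.counts @ L[:, 0])

    res = minimize_scalar(neg_scale, bounds=(math.log(0.02), math.log(100.0)),
                          method="bounded", options={"xatol": 0.05})
    scale0 = math.exp(res.x)

    def neg_omega(log_w):
        L = engine.class_logliks(np.array([math.exp(log_w)]), one, scale0)
        return -float(engine.counts @ L[:, 0])

    res = minimize_scalar(neg_omega, bounds=(math.log(1e-3), math.log(20.0)),
                          method="bounded", options={"xatol": 0.05})
    return scale0, math.exp(res.x)


def _fit_homogeneous(engine, omega0: float, scale0: float) -> float:
    """Joint (omega, scale) single-class ML fit; the nested baseline for the
    heterogeneity gate."""
    one = np.ones(1)

    def neg(theta):
        L = engine.class_logliks(np.array([math.exp(theta[0])]), one,
                                 math.exp(theta[1]))
        return -float(engine.counts @ L[:, 0])

    res = minimize(neg, np.log([max(omega0, 1e-4), scale0]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxfev": 200})
    return -float(res.fun)


def fit_rel(codon_aln: CodonAlignment, tree, constraints: NucleotideConstraintSet,
            n_classes: int = 3, freq_method: str = "F3x4",
            n_starts: int = 5, maxfev: int = 400, nuc_rounds: int = 2,
            ref_map=None, strong_threshold: float = STRONG_BF,
            weak_threshold: float = WEAK_BF, dtype=np.float32) -> RelFit:
    """Fit the 3x3 (dN, dS) random-effects codon model and classify sites."""
    if n_classes != 3:
        raise ValueError("grid is fixed at 3 dN x 3 dS classes")
    if len(codon_aln.identifiers) < 3:
        raise ValueError("need at least 3 sequences")

    nuc_values, fitted_tree, _, _ = fit_nucleotide(
        codon_aln.base, tree, constraints, rounds=nuc_rounds)
    nuc_rates = constraints.rates(nuc_values)
    pi_codon = estimate_codon_frequencies(codon_aln, method=freq_method)

    engine = _CodonMixtureLikelihood(fitted_tree, codon_aln, nuc_rates, pi_codon,
                                     dtype=dtype)
    scale0, omega0 = _stage2_init(engine)

    best = None
    start_log = []
    budget = max(40, maxfev // max(1, n_starts))
    for dn_mult, ds0 in _STARTS[:max(1, n_starts)]:
        dn0 = tuple(max(m * omega0, 1e-4) for m in dn_mult)
        theta0 = np.log(np.array(list(dn0) + list(ds0) + [scale0]))
        state = {"w": None}

        def neg(theta):
            dn = np.exp(theta[0:3])
            ds = np.array([math.exp(theta[3]), 1.0, math.exp(theta[4])])
            scale = math.exp(theta[5])
            if scale > 200 or np.any(dn > 500) or np.any(ds > 500):
                return 1e10
            logL = engine.class_logliks(dn, ds, scale)
            w, ll, _ = _em_weights(logL, engine.counts, state["w"])
            state["w"] = w
            return -ll

        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 5e-3, "maxfev": budget})
        start_log.append({"start": (dn0, ds0), "loglik": -float(res.fun),
                          "nfev": int(res.nfev), "converged": bool(res.success)})
        if best is None or -res.fun > best[0]:
            best = (-float(res.fun), res.x, bool(res.success))

    loglik, theta, converged = best
    if not converged:
        warnings.warn("REL grid optimizer hit its evaluation budget; "
                      "reporting best values found")
    dn = np.exp(theta[0:3])
    ds = np.array([math.exp(theta[3]), 1.0, math.exp(theta[4])])
    scale = math.exp(theta[5])
    logL = engine.class_logliks(dn, ds, scale)
    w, loglik, post_patterns = _em_weights(logL, engine.counts, max_iter=2000)

    weights = w.reshape(3, 3)
    # report on the weighted-mean-dS = 1 scale; keep raw values alongside
    ds_marg = weights.sum(axis=0)
    mean_ds = float(ds_marg @ ds)
    grid = RateClassGrid(dn_values=dn / mean_ds if mean_ds > 0 else dn,
                         ds_values=ds / mean_ds if mean_ds > 0 else ds,
                         weights=weights, dn_values_raw=dn.copy(),
                         ds_values_raw=ds.copy())

    site_post = post_patterns[engine.inverse].reshape(-1, 3, 3)
    n_sites = site_post.shape[0]
    offset_residues = codon_aln.origin_offset // 3
    if ref_map is not None:
        labels = [ref_map.residue(s) for s in range(1, n_sites + 1)]
        labels = [l if l is not None else -1 for l in labels]
    else:
        labels = [s + offset_residues for s in range(1, n_sites + 1)]

    ll_hom = _fit_homogeneous(engine, omega0, scale0)
    gain = loglik - ll_hom
    fit = RelFit(grid=grid, nucleotide_mles=nuc_rates,
                 codon_frequencies=pi_codon, branch_scale=scale * mean_ds,
                 log_likelihood=loglik, tree=fitted_tree,
                 constraints=constraints, site_posteriors_matrix=site_post,
                 converged=converged, start_log=start_log, site_labels=labels,
                 heterogeneity_gain=gain,
                 selection_gate_passed=bool(gain > HETEROGENEITY_GATE))
    fit.prior_positive = (float(weights[grid.positive_mask].sum())
                          if fit.selection_gate_passed else 0.0)
    fit.per_site = classify_sites(fit, strong_threshold, weak_threshold)
    return fit


# ---------------------------------------------------------------------------
# per-site inference
# ---------------------------------------------------------------------------

def site_posteriors(fit: RelFit) -> np.ndarray:
    """(n_sites, 3, 3) posterior class membership; each site sums to 1."""
    return fit.site_posteriors_matrix


def posterior_positive(fit: RelFit) -> np.ndarray:
    mask = fit.grid.positive_mask
    return fit.site_posteriors_matrix[:, mask].sum(axis=1)


def bayes_factor_positive(fit: RelFit, site: int) -> float:
    """Posterior-odds / prior-odds that the (1-based) site has dN > dS."""
    prior = fit.prior_positive
    if prior <= 0.0 or prior >= 1.0 - 1e-9:
        return math.nan
    post = float(posterior_positive(fit)[site - 1])
    if post >= 1.0:
        return math.inf
    return (post / (1.0 - post)) / (prior / (1.0 - prior))


def classify_sites(fit: RelFit, strong_threshold: float = STRONG_BF,
                   weak_threshold: float = WEAK_BF) -> list[SiteSelection]:
    prior = fit.prior_positive
    post = posterior_positive(fit)
    out = []
    for s in range(len(post)):
        if prior <= 0.0 or prior >= 1.0 - 1e-9:
            bf, cat = math.nan, "none"
        else:
            p = float(post[s])
            bf = math.inf if p >= 1.0 else (
                (p / (1.0 - p)) / (prior / (1.0 - prior)))
            if bf >= strong_threshold:
                cat = "strong"
            elif bf >= weak_threshold:
                cat = "weak"
            elif p < prior:
                cat = "negative"
            else:
                cat = "none"
        out.append(SiteSelection(site=fit.site_labels[s],
                                 posterior_positive=float(post[s]),
                                 bayes_factor=bf, category=cat))
    return out
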