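"""Branch-category codon substitution model (GY94-style) with ML fitting.

The rate matrix over sense codons follows Goldman-Yang: single-nucleotide
changes only, target-codon frequency ``pi_j``, a transition/transversion
ratio ``kappa`` and a nonsynonymous/synonymous ratio ``omega``. Each branch
of a labeled tree evolves under the omega of its category ("variable-ratio
branch model"); branch lengths are free per branch in expected substitutions
per codon. The likelihood is computed by Felsenstein pruning over site
patterns, with analytic gradients (branch lengths via an up/down pass; kappa
and the omegas via eigen-decomposition divided differences), and maximized
by bounded quasi-Newton with multi-start.

Per-category dN and dS are decomposed from the fitted parameters through the
synonymous flux fraction of each category's rate matrix and the mutational-
opportunity site counts S and N (S + N = 3 per codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .seqio import (
    GAP_CODON,
    CodonAlignment,
    GeneticCode,
    InsufficientTaxaError,
    LabeledTree,
    ValidationError,
    attach_labels,
    is_unambiguous,
    prune_labeled_tree,
    tip_labels,
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class CategoryAbsentError(ValidationError):
    """A category of the labeling alphabet is missing from the (pruned) tree."""


class NumericError(ArithmeticError):
    """Non-finite likelihood."""


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _pair_structure(code_id: int):
    """Index arrays over single-nucleotide-difference sense-codon pairs."""
    from .seqio import get_genetic_code

    code = get_genetic_code(code_id)
    sense = code.sense_codons
    n = len(sense)
    ii, jj, ts, syn = [], [], [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(sense[i], sense[j]) if a != b]
            if len(diff) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(diff[0] in _TRANSITIONS)
            syn.append(code.codon_to_aa[sense[i]] == code.codon_to_aa[sense[j]])
    return (np.array(ii), np.array(jj), np.array(ts, dtype=bool),
            np.array(syn, dtype=bool))


def _raw_rates(kappa: float, omega: float, pi: np.ndarray, code: GeneticCode):
    """Unscaled off-diagonal entries q~_ij and the pair index arrays."""
    ii, jj, ts, syn = _pair_structure(code.code_id)
    vals = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    return ii, jj, ts, syn, vals


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode) -> np.ndarray:
    """Scaled GY94 generator: rows sum to 0 and the expected substitution
    rate at stationarity is 1 (branch lengths in substitutions per codon)."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (code.n_sense,):
        raise ValidationError(f"pi must have length {code.n_sense}")
    if np.any(pi <= 0):
        raise ValidationError("pi entries must be positive (apply pseudo-counts upstream)")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValidationError("pi must sum to 1")
    if kappa <= 0 or omega < 0:
        raise ValidationError("kappa must be > 0 and omega >= 0")
    n = code.n_sense
    ii, jj, _, _, vals = _raw_rates(kappa, omega, pi, code)
    q = np.zeros((n, n))
    q[ii, jj] = vals
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float(pi @ np.diag(q))
    if rate <= 0:
        raise ValidationError("degenerate rate matrix (zero total flux)")
    return q / rate


def syn_flux_fraction(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode) -> float:
    """Fraction of the stationary substitution flux that is synonymous."""
    ii, jj, _, syn, vals = _raw_rates(kappa, omega, np.asarray(pi, float), code)
    flux = pi[ii] * vals
    return float(flux[syn].sum() / flux.sum())


def count_sites(pi: np.ndarray, kappa: float, code: GeneticCode) -> tuple:
    """Synonymous/nonsynonymous sites per codon from mutational opportunity:
    the synonymous flux fraction of the neutral (omega = 1) process, times 3."""
    fs = syn_flux_fraction(kappa, 1.0, np.asarray(pi, float), code)
    s = 3.0 * fs
    return s, 3.0 - s


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_FREQ_FLOOR = 1e-6


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """PAML-style F3x4: position-specific nucleotide frequencies multiplied
    per codon, stops excluded, renormalized over sense codons. Zero-frequency
    nucleotides are floored at 1e-6 before renormalization."""
    counts = np.zeros((3, 4))
    for taxon in alignment.taxa:
        for codon in alignment.codons(taxon):
            if codon == GAP_CODON or not is_unambiguous(codon):
                continue
            for pos, nuc in enumerate(codon):
                counts[pos, _NUC_INDEX[nuc]] += 1
    if counts.sum() == 0:
        raise ValidationError(f"{alignment.gene_id}: no unambiguous codons")
    freqs = np.maximum(counts / counts.sum(axis=1, keepdims=True), _FREQ_FLOOR)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    return _codon_pi_from_positional(freqs, alignment.code)


def f1x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Like F3x4 but with a single nucleotide distribution for all positions."""
    counts = np.zeros(4)
    for taxon in alignment.taxa:
        for codon in alignment.codons(taxon):
            if codon == GAP_CODON or not is_unambiguous(codon):
                continue
            for nuc in codon:
                counts[_NUC_INDEX[nuc]] += 1
    if counts.sum() == 0:
        raise ValidationError(f"{alignment.gene_id}: no unambiguous codons")
    freqs = np.maximum(counts / counts.sum(), _FREQ_FLOOR)
    freqs = freqs / freqs.sum()
    return _codon_pi_from_positional(np.tile(freqs, (3, 1)), alignment.code)


def empirical_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies with a pseudo-count floor."""
    code = alignment.code
    counts = np.zeros(code.n_sense)
    for taxon in alignment.taxa:
        for codon in alignment.codons(taxon):
            idx = code.codon_index.get(codon)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ValidationError(f"{alignment.gene_id}: no unambiguous codons")
    pi = np.maximum(counts / counts.sum(), _FREQ_FLOOR)
    return pi / pi.sum()


def _codon_pi_from_positional(freqs: np.ndarray, code: GeneticCode) -> np.ndarray:
    pi = np.array([
        freqs[0, _NUC_INDEX[c[0]]] * freqs[1, _NUC_INDEX[c[1]]] * freqs[2, _NUC_INDEX[c[2]]]
        for c in code.sense_codons
    ])
    return pi / pi.sum()


FREQUENCY_MODELS = {
    "F3x4": f3x4_frequencies,
    "F1x4": f1x4_frequencies,
    "empirical": empirical_frequencies,
}


# ---------------------------------------------------------------------------
# Eigen machinery for the reversible generator
# ---------------------------------------------------------------------------

class _Eig:
    """Eigendecomposition of a reversible generator via symmetrization.

    P(t) = A diag(e^{lam t}) B with A = D^{-1/2} U, B = U^T D^{1/2},
    D = diag(pi); derivative matrices come from divided differences.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d_sqrt = np.sqrt(pi)
        sym = (q * d_sqrt[:, None]) / d_sqrt[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, u = np.linalg.eigh(sym)
        self.lam = lam
        self.A = u / d_sqrt[:, None]
        self.B = u.T * d_sqrt[None, :]
        self.pi = pi

    def transition(self, t: float) -> np.ndarray:
        return (self.A * np.exp(self.lam * t)) @ self.B

    def sym_project(self, dq: np.ndarray) -> np.ndarray:
        """W = U^T (D^{1/2} dQ D^{-1/2}) U for a reversible perturbation dQ."""
        d_sqrt = np.sqrt(self.pi)
        c = (dq * d_sqrt[:, None]) / d_sqrt[None, :]
        c = 0.5 * (c + c.T)
        u = self.B.T / d_sqrt[:, None]  # recover U
        return u.T @ c @ u

    def divided_differences(self, t: float) -> np.ndarray:
        lam = self.lam
        e = np.exp(lam * t)
        diff = lam[:, None] - lam[None, :]
        ediff = e[:, None] - e[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = ediff / diff
        near = np.abs(diff) < 1e-10
        mean_e = 0.5 * (e[:, None] + e[None, :])
        phi[near] = t * mean_e[near]
        return phi


def _dq_dlog(kappa: float, omega: float, pi: np.ndarray, code: GeneticCode):
    """d(scaled Q)/d log kappa and d(scaled Q)/d log omega (analytic)."""
    n = code.n_sense
    ii, jj, ts, syn, vals = _raw_rates(kappa, omega, pi, code)
    flux = pi[ii] * vals
    r = float(flux.sum())
    q_off = np.zeros((n, n))
    q_off[ii, jj] = vals
    out = []
    for mask in (ts, ~syn):  # d/dlog kappa, d/dlog omega
        dvals = np.where(mask, vals, 0.0)
        dr = float((pi[ii] * dvals).sum())
        dq = np.zeros((n, n))
        dq[ii, jj] = dvals
        np.fill_diagonal(dq, -dq.sum(axis=1))
        q_full = q_off.copy()
        np.fill_diagonal(q_full, -q_off.sum(axis=1))
        out.append(dq / r - q_full * (dr / r ** 2))
    return out  # [dQ/dlogkappa, dQ/dlogomega]


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

MISSING_CODE = -1


@dataclass
class CodonModelParams:
    """Parameters of the branch-category model.

    ``branch_lengths`` may be None, meaning "use the labeled tree's own
    branch lengths" (the common case for simulation and one-shot evaluation).
    """

    kappa: float
    omega_by_category: dict
    pi: np.ndarray
    branch_lengths: np.ndarray | None = None


@dataclass
class _Edge:
    node_index: int
    parent_index: int
    category_index: int
    length: float
    tip_taxon: str | None
    label: str  # human-readable branch id


def _collapse_root_bifurcation(ltree: LabeledTree) -> LabeledTree:
    """Unroot for likelihood computation: a binary root is collapsed so its
    two edges become one branch (lengths summed), as the reversible model
    cannot identify the split. The merged branch takes the category of the
    longer merged segment (tie: the surviving child side). A two-leaf tree
    is left as is (the rooted form is already minimal)."""
    root = ltree.tree.seed_node
    kids = root.child_nodes()
    if len(kids) != 2:
        return ltree
    internal = [k for k in kids if not k.is_leaf()]
    if not internal:
        return ltree
    work = ltree.copy()
    root = work.tree.seed_node
    kids = root.child_nodes()
    new_root = next(k for k in kids if not k.is_leaf())
    other = kids[0] if kids[1] is new_root else kids[1]
    t_new, t_other = new_root.edge.length or 0.0, other.edge.length or 0.0
    if t_new > t_other:
        other.category = new_root.category
    root.remove_child(other)
    root.remove_child(new_root)
    new_root.parent_node = None
    work.tree.seed_node = new_root
    new_root.add_child(other)
    other.edge.length = t_new + t_other
    new_root.edge.length = 0.0
    return LabeledTree(tree=work.tree, alphabet=work.alphabet)


class LikelihoodEngine:
    """Pruning likelihood and gradient for one gene on one labeled tree.

    Site patterns are aliased (identical columns collapsed with weights);
    gap/ambiguous codons integrate to one (missing data). The tree is used
    as rooted with root prior pi; under the reversible model the likelihood
    is invariant to root placement.
    """

    def __init__(self, alignment: CodonAlignment, ltree: LabeledTree,
                 freq_model: str = "F3x4", pi: np.ndarray | None = None):
        shared = sorted(set(alignment.taxa) & set(tip_labels(ltree.tree)))
        # 2 taxa suffice for likelihood evaluation; fitting requires >= 3
        if len(shared) < 2:
            raise InsufficientTaxaError(
                f"{alignment.gene_id}: only {len(shared)} taxa shared between "
                "alignment and tree")
        if set(shared) != set(tip_labels(ltree.tree)):
            ltree = prune_labeled_tree(ltree, shared)
        alignment = alignment.subset(shared)
        self.alignment = alignment
        self.ltree = _collapse_root_bifurcation(ltree)
        self.code = alignment.code
        self.categories = tuple(self.ltree.alphabet)
        missing_cats = set(self.categories) - set(self.ltree.categories_present())
        if missing_cats:
            raise CategoryAbsentError(
                f"{alignment.gene_id}: categories absent from pruned tree: "
                f"{sorted(missing_cats)}")
        if pi is None:
            pi = FREQUENCY_MODELS[freq_model](alignment)
        self.pi = np.asarray(pi, dtype=float)
        self._build_tree_arrays()
        self._build_patterns()

    # -- construction ------------------------------------------------------

    def _build_tree_arrays(self):
        tree = self.ltree.tree
        cat_index = {c: i for i, c in enumerate(self.categories)}
        nodes = list(tree.postorder_node_iter())
        self._node_index = {n: i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = self._node_index[tree.seed_node]
        self.children: list = [[] for _ in nodes]
        self.edges: list = []
        self.edge_of_node = np.full(self.n_nodes, -1, dtype=int)
        for node in nodes:
            i = self._node_index[node]
            if node is tree.seed_node:
                continue
            p = self._node_index[node.parent_node]
            self.children[p].append(i)
            if node.is_leaf():
                tip = node.taxon.label
                label = tip
            else:
                tip = None
                label = "clade{" + ",".join(sorted(
                    leaf.taxon.label for leaf in node.leaf_iter())) + "}"
            self.edge_of_node[i] = len(self.edges)
            self.edges.append(_Edge(
                node_index=i, parent_index=p,
                category_index=cat_index[node.category],
                length=float(node.edge.length or 0.0),
                tip_taxon=tip, label=label,
            ))
        self.n_edges = len(self.edges)
        self.tip_index = {e.tip_taxon: e.node_index
                          for e in self.edges if e.tip_taxon is not None}

    def _build_patterns(self):
        aln, code = self.alignment, self.code
        n_taxa, n_codons = len(aln.taxa), aln.n_codons
        mat = np.full((n_taxa, n_codons), MISSING_CODE, dtype=np.int16)
        for r, taxon in enumerate(aln.taxa):
            for c, codon in enumerate(aln.codons(taxon)):
                idx = code.codon_index.get(codon)
                if idx is not None:
                    mat[r, c] = idx
        patterns, weights = np.unique(mat, axis=1, return_counts=True)
        self.pattern_codes = {taxon: patterns[r] for r, taxon in enumerate(aln.taxa)}
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]
        self.n_codons = n_codons

    # -- parameter packing -------------------------------------------------

    @property
    def n_params(self) -> int:
        return 1 + len(self.categories) + self.n_edges

    def edge_lengths(self) -> np.ndarray:
        """The labeled tree's own branch lengths, in edge order."""
        return np.array([e.length for e in self.edges])

    def initial_lengths(self) -> np.ndarray:
        """Optimizer starting lengths: tree lengths floored away from zero."""
        return np.array([max(e.length, 1e-6) for e in self.edges])

    # -- likelihood & gradient --------------------------------------------

    def _category_eigs(self, kappa, omegas):
        eigs, dqs = [], []
        for w in omegas:
            q = build_rate_matrix(kappa, w, self.pi, self.code)
            eigs.append(_Eig(q, self.pi))
            dqs.append(_dq_dlog(kappa, w, self.pi, self.code))
        return eigs, dqs

    def log_likelihood(self, kappa, omegas, lengths) -> float:
        eigs, _ = self._category_eigs(kappa, np.asarray(omegas, float))
        lnl, *_ = self._down_pass(eigs, np.asarray(lengths, float))
        return lnl

    def _down_pass(self, eigs, lengths):
        npat, S = self.n_patterns, self.code.n_sense
        down = [None] * self.n_nodes
        logsc = [None] * self.n_nodes
        Y = [None] * self.n_nodes   # down_child @ B.T per edge child
        E = [None] * self.n_nodes   # exp(lam * t) per edge child
        M = [None] * self.n_nodes   # message to parent per edge child
        for i in range(self.n_nodes):
            if not self.children[i]:
                continue
            vec = np.ones((npat, S))
            ls = np.zeros(npat)
            for ci in self.children[i]:
                e = self.edges[self.edge_of_node[ci]]
                eig = eigs[e.category_index]
                t = lengths[self.edge_of_node[ci]]
                exp_lam = np.exp(eig.lam * t)
                if e.tip_taxon is not None:
                    codes = self.pattern_codes[e.tip_taxon]
                    y = np.where(codes[:, None] == MISSING_CODE,
                                 eig.B.sum(axis=1)[None, :],
                                 eig.B.T[np.maximum(codes, 0)])
                else:
                    y = down[ci] @ eig.B.T
                    ls = ls + logsc[ci]
                Y[ci], E[ci] = y, exp_lam
                # eigen round-off can turn transition probabilities below
                # ~1e-14 negative; clamp so likelihoods stay non-negative
                m = np.maximum((y * exp_lam) @ eig.A.T, 0.0)
                M[ci] = m
                vec = vec * m
            scale = np.maximum(vec.max(axis=1), 1e-300)
            down[i] = vec / scale[:, None]
            logsc[i] = ls + np.log(scale)
        root = self.root_index
        site_l = down[root] @ self.pi
        if not np.all(np.isfinite(site_l)):
            bad = int(np.argmin(np.isfinite(site_l)))
            raise NumericError(f"non-finite site likelihood at pattern {bad}")
        # patterns numerically indistinguishable from impossible get a hard
        # but finite penalty; the optimizer moves away from such regions
        site_l = np.maximum(site_l, 1e-290)
        lnl = float(self.weights @ (np.log(site_l) + logsc[root]))
        return lnl, down, Y, E, M

    def log_likelihood_and_grad(self, kappa, omegas, lengths):
        """lnL and its gradient w.r.t. (log kappa, log omegas, log lengths)."""
        omegas = np.asarray(omegas, float)
        lengths = np.asarray(lengths, float)
        eigs, dqs = self._category_eigs(kappa, omegas)
        lnl, down, Y, E, M = self._down_pass(eigs, lengths)
        npat, S = self.n_patterns, self.code.n_sense
        w = self.weights
        # preorder "out" vectors, indexed by the parent-end state of each edge
        out = [None] * self.n_nodes
        out[self.root_index] = np.tile(self.pi, (npat, 1))
        order = list(range(self.n_nodes))[::-1]  # reverse postorder = preorder
        g_t = np.zeros(self.n_edges)
        g_kappa = 0.0
        g_omega = np.zeros(len(omegas))
        # per category, precompute W matrices for dlog kappa / dlog omega
        Wk, Ww = [], []
        for eig, (dqk, dqw) in zip(eigs, dqs):
            Wk.append(eig.sym_project(dqk))
            Ww.append(eig.sym_project(dqw))
        for i in order:
            if not self.children[i]:
                continue
            kids = self.children[i]
            if i == self.root_index:
                outlik = out[i]
            else:
                # push the parent-end out vector through this node's own
                # branch so it is indexed by the state at node i
                e_i = self.edges[self.edge_of_node[i]]
                eig_i = eigs[e_i.category_index]
                outlik = ((out[i] @ eig_i.A) * E[i]) @ eig_i.B
                # rare-codon pi entries make A/B ill-scaled; keep out O(1)
                outlik = np.maximum(outlik, 0.0)
                sc = np.maximum(outlik.max(axis=1), 1e-300)
                outlik = outlik / sc[:, None]
            for ci in kids:
                vec = outlik
                for sib in kids:
                    if sib is not ci:
                        vec = vec * M[sib]
                scale = np.maximum(vec.max(axis=1), 1e-300)
                out[ci] = vec / scale[:, None]
            for ci in kids:
                ei = self.edge_of_node[ci]
                e = self.edges[ei]
                eig = eigs[e.category_index]
                t = lengths[ei]
                y, exp_lam = Y[ci], E[ci]
                z = out[ci] @ eig.A  # (npat, S) in eigenbasis
                denom = np.einsum("ps,ps->p", z, y * exp_lam)
                # patterns whose conditional likelihood underflowed are held
                # at the objective's floor; their gradient contribution is 0
                ok = denom > 1e-250
                denom = np.where(ok, denom, 1.0)

                def ratio(numer):
                    return np.where(ok, numer / denom, 0.0)

                # branch length (log scale): dP/dt brings a factor lam
                numer_t = np.einsum("ps,ps->p", z, y * (eig.lam * exp_lam))
                g_t[ei] = float(w @ ratio(numer_t)) * t
                # kappa / omega via divided differences
                phi = eig.divided_differences(t)
                dk = y @ (Wk[e.category_index] * phi).T
                g_kappa += float(w @ ratio(np.einsum("ps,ps->p", z, dk)))
                dw = y @ (Ww[e.category_index] * phi).T
                g_omega[e.category_index] += float(
                    w @ ratio(np.einsum("ps,ps->p", z, dw)))
        grad = np.concatenate([[g_kappa], g_omega, g_t])
        return lnl, grad


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

BOUNDS = {"omega": (1e-4, 20.0), "kappa": (0.1, 50.0), "t": (1e-8, 30.0)}


@dataclass
class FitConfig:
    """Optimizer settings for the branch-model fit."""

    freq_model: str = "F3x4"
    n_starts: int = 2
    maxiter: int = 1000
    seed: int = 0
    jitter_sd: float = 0.3        # lognormal sd of multi-start jitter
    grad_tol: float = 1e-4        # convergence: inf-norm of log-scale gradient
    agree_tol: float = 1e-4       # convergence: lnL spread of best two starts
    init_kappa: float = 2.0
    init_omega: float = 0.2
    init: dict | None = None      # optional warm start {kappa, omegas, lengths}


@dataclass
class CategoryEstimates:
    """Per-gene ML fit: omega, dN, dS per branch category plus nuisances."""

    gene_id: str
    categories: tuple
    omega: dict
    dN: dict
    dS: dict
    kappa: float
    lnL: float
    n_codons: int
    converged: bool
    n_taxa: int = 0
    sites_S: float = 0.0
    sites_N: float = 0.0
    grad_norm: float = np.nan
    lnl_spread: float = np.nan
    seed: int = 0
    branch_records: list = field(default_factory=list)  # (branch, category, t, dN_b, dS_b)


def collapse_to_single_category(ltree: LabeledTree, label: str = "all") -> LabeledTree:
    work = ltree.copy()
    labels = {n: label for n in work.tree.preorder_node_iter()
              if n is not work.tree.seed_node}
    return attach_labels(work.tree, labels, (label,))


def log_likelihood(alignment: CodonAlignment, ltree: LabeledTree,
                   params: CodonModelParams, freq_model: str = "F3x4") -> float:
    """One-shot pruning log-likelihood for given parameters."""
    engine = LikelihoodEngine(alignment, ltree, freq_model=freq_model, pi=params.pi)
    lengths = (np.asarray(params.branch_lengths, float)
               if params.branch_lengths is not None else engine.edge_lengths())
    omegas = [params.omega_by_category[c] for c in engine.categories]
    return engine.log_likelihood(params.kappa, omegas, lengths)


def fit_branch_model(alignment: CodonAlignment, ltree: LabeledTree,
                     config: FitConfig | None = None) -> CategoryEstimates:
    """Maximize the branch-category likelihood and decompose dN/dS.

    Optimizes kappa, one omega per category and all branch lengths jointly
    (L-BFGS-B on the log scale with analytic gradients). The first start
    uses the input tree's branch lengths; further starts jitter
    multiplicatively. Convergence requires a small projected gradient and,
    with >= 2 starts, agreement of the best two log-likelihoods.
    """
    config = config or FitConfig()
    engine = LikelihoodEngine(alignment, ltree, freq_model=config.freq_model)
    if len(engine.alignment.taxa) < 3:
        raise InsufficientTaxaError(
            f"{alignment.gene_id}: need >= 3 taxa to fit, got "
            f"{len(engine.alignment.taxa)}")
    n_cat = len(engine.categories)
    rng = np.random.default_rng(config.seed)

    lo = np.log(np.concatenate([[BOUNDS["kappa"][0]],
                                np.full(n_cat, BOUNDS["omega"][0]),
                                np.full(engine.n_edges, BOUNDS["t"][0])]))
    hi = np.log(np.concatenate([[BOUNDS["kappa"][1]],
                                np.full(n_cat, BOUNDS["omega"][1]),
                                np.full(engine.n_edges, BOUNDS["t"][1])]))

    if config.init is not None:
        base = np.concatenate([
            [config.init.get("kappa", config.init_kappa)],
            np.asarray(config.init.get(
                "omegas", np.full(n_cat, config.init_omega)), float),
            np.asarray(config.init.get("lengths", engine.initial_lengths()), float),
        ])
    else:
        base = np.concatenate([[config.init_kappa],
                               np.full(n_cat, config.init_omega),
                               engine.initial_lengths()])
    x_base = np.clip(np.log(base), lo, hi)

    def objective(x):
        p = np.exp(x)
        lnl, grad = engine.log_likelihood_and_grad(p[0], p[1:1 + n_cat],
                                                   p[1 + n_cat:])
        return -lnl, -grad

    def jittered_start():
        # rate parameters explore more than the (well-initialized) lengths
        noise = np.concatenate([
            rng.normal(0.0, config.jitter_sd, 1 + n_cat),
            rng.normal(0.0, 0.1, engine.n_edges),
        ])
        return np.clip(x_base + noise, lo, hi)

    results = []
    n_starts = max(1, config.n_starts)
    attempts = 0
    while len(results) < n_starts and attempts < 2 * n_starts + 2:
        x0 = x_base if attempts == 0 else jittered_start()
        attempts += 1
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"maxiter": config.maxiter, "ftol": 1e-14,
                                "gtol": 1e-6, "maxcor": 30})
        # a start stranded far above the current best (line-search failure in
        # a numerically floored region) is discarded and redrawn
        if results and res.fun > min(r.fun for r in results) + 100.0:
            continue
        if results and res.fun < min(r.fun for r in results) - 100.0:
            results = [r for r in results if r.fun <= res.fun + 100.0]
        results.append(res)
    results.sort(key=lambda r: r.fun)
    best = results[0]
    # projected gradient: ignore components pushing outward at active bounds
    g = best.jac.copy()
    at_lo = best.x <= lo + 1e-12
    at_hi = best.x >= hi - 1e-12
    g[at_lo & (g > 0)] = 0.0
    g[at_hi & (g < 0)] = 0.0
    grad_norm = float(np.max(np.abs(g)))
    spread = (abs(results[0].fun - results[1].fun)
              if len(results) > 1 else 0.0)
    converged = grad_norm < config.grad_tol and spread < config.agree_tol

    p = np.exp(best.x)
    kappa = float(p[0])
    omegas = p[1:1 + n_cat]
    lengths = p[1 + n_cat:]
    est = decompose_dn_ds(engine, kappa, omegas, lengths)
    return CategoryEstimates(
        gene_id=alignment.gene_id,
        categories=engine.categories,
        omega={c: float(w) for c, w in zip(engine.categories, omegas)},
        dN=est["dN"], dS=est["dS"],
        kappa=kappa, lnL=float(-best.fun),
        n_codons=engine.n_codons,
        converged=bool(converged),
        n_taxa=len(engine.alignment.taxa),
        sites_S=est["S"], sites_N=est["N"],
        grad_norm=grad_norm, lnl_spread=float(spread),
        seed=config.seed,
        branch_records=est["branches"],
    )


def decompose_dn_ds(engine: LikelihoodEngine, kappa: float,
                    omegas: np.ndarray, lengths: np.ndarray) -> dict:
    """Per-category dN and dS from fitted parameters.

    For a branch of length t in category c, the synonymous flux fraction
    fS(omega_c) splits t into expected synonymous and nonsynonymous
    substitutions per codon; dividing by the per-codon site proportions
    S/3 and N/3 puts both on per-site scales. Category values are sums over
    the category's branches. At omega = 1, dN_b = dS_b = t_b.
    """
    code, pi = engine.code, engine.pi
    s_sites, n_sites = count_sites(pi, kappa, code)
    fs = {ci: syn_flux_fraction(kappa, float(w), pi, code)
          for ci, w in enumerate(omegas)}
    dn = {c: 0.0 for c in engine.categories}
    ds = {c: 0.0 for c in engine.categories}
    branches = []
    for ei, e in enumerate(engine.edges):
        c = engine.categories[e.category_index]
        t = float(lengths[ei])
        f = fs[e.category_index]
        ds_b = t * f / (s_sites / 3.0)
        dn_b = t * (1.0 - f) / (n_sites / 3.0)
        ds[c] += ds_b
        dn[c] += dn_b
        branches.append((e.label, c, t, dn_b, ds_b))
    return {"dN": dn, "dS": ds, "S": s_sites, "N": n_sites, "branches": branches}
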