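"""Ancestral-state estimation for discrete traits and branch labeling.

Fits a continuous-time Markov (Mk) model to tip states, computes marginal
ancestral state probabilities by the pruning algorithm with re-rooting,
draws stochastic character maps (posterior trait histories along branches),
and converts branch-state occupancies into a single per-branch category
labeling for the branch codon models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .seqio import (
    InsufficientTaxaError,
    LabeledTree,
    ValidationError,
    attach_labels,
    prune_to_taxa,
    tip_labels,
)


class DegenerateTraitError(ValueError):
    """Trait constant across tips: nothing to fit, label branches directly."""


@dataclass
class MkFit:
    """Maximum-likelihood Mk fit with marginal ancestral probabilities.

    ``marginals`` maps node -> probability vector over ``alphabet`` (nodes of
    ``tree``, which is the input tree pruned to taxa with observed states).
    Root prior is the stationary distribution of the fitted rate matrix.
    """

    trait_name: str
    alphabet: tuple
    rate_matrix: np.ndarray
    log_likelihood: float
    tree: dendropy.Tree
    marginals: dict = field(repr=False)
    root_prior: np.ndarray = field(repr=False)
    converged: bool = True
    model: str = "ER"


def _stationary_distribution(q: np.ndarray) -> np.ndarray:
    k = q.shape[0]
    a = np.vstack([q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 1e-12, None)
    return pi / pi.sum()


def _mk_q(rates: np.ndarray, k: int, model: str) -> np.ndarray:
    q = np.zeros((k, k))
    if model == "ER":
        q[:] = rates[0]
    elif model == "ARD":
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValidationError(f"unknown Mk model {model!r}")
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _postorder_conditionals(tree, tip_vec, q):
    """Pruning pass: node -> (conditional likelihoods below node, P on the
    branch above node). Returns (down, P_by_node)."""
    down, p_by_node = {}, {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = tip_vec[node.taxon.label].copy()
        else:
            vec = np.ones(q.shape[0])
            for child in node.child_nodes():
                p = expm(q * (child.edge.length or 0.0))
                p_by_node[child] = p
                vec = vec * (p @ down[child])
            down[node] = vec
    return down, p_by_node


def mk_log_likelihood(tree, tip_states: dict, alphabet, q: np.ndarray,
                      root_prior: np.ndarray | None = None) -> float:
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    tip_vec = {}
    for taxon, state in tip_states.items():
        v = np.zeros(k)
        v[index[state]] = 1.0
        tip_vec[taxon] = v
    down, _ = _postorder_conditionals(tree, tip_vec, q)
    prior = _stationary_distribution(q) if root_prior is None else root_prior
    lik = float(prior @ down[tree.seed_node])
    if lik <= 0:
        return -np.inf
    return np.log(lik)


def fit_mk(tree: dendropy.Tree, tip_states: dict, trait_name: str = "trait",
           model: str = "ER", alphabet=None) -> MkFit:
    """Fit an Mk model and compute marginal ancestral probabilities.

    Tips with missing states are pruned before fitting (>= 3 observed states
    required); a constant trait raises :class:`DegenerateTraitError` since
    direct labeling is then the right tool.
    """
    observed = {t: s for t, s in tip_states.items() if s is not None}
    if alphabet is None:
        alphabet = tuple(sorted(set(observed.values())))
    else:
        alphabet = tuple(alphabet)
        bad = set(observed.values()) - set(alphabet)
        if bad:
            raise ValidationError(f"tip states outside alphabet: {sorted(bad)}")
    if len(observed) < 3:
        raise InsufficientTaxaError(f"need >= 3 tips with observed states, got {len(observed)}")
    if len(set(observed.values())) < 2:
        raise DegenerateTraitError(
            f"trait {trait_name!r} is constant across tips; use direct labeling"
        )
    work = prune_to_taxa(tree, observed) if set(tip_labels(tree)) != set(observed) else tree
    k = len(alphabet)
    n_rates = 1 if model == "ER" else k * (k - 1)
    tree_len = sum((e.length or 0.0) for e in work.preorder_edge_iter() if e.length)
    # expected-one-transition starting rate; optimized on the log scale
    x0 = np.full(n_rates, np.log(max(1.0 / max(tree_len, 1e-6), 1e-4)))

    def nll(x):
        q = _mk_q(np.exp(x), k, model)
        return -mk_log_likelihood(work, observed, alphabet, q)

    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(np.log(1e-8), np.log(1e4))] * n_rates)
    rates = np.exp(res.x)
    q = _mk_q(rates, k, model)
    prior = _stationary_distribution(q)
    lnl = mk_log_likelihood(work, observed, alphabet, q, prior)
    marginals = _marginal_ancestral_states(work, observed, alphabet, q, prior)
    return MkFit(
        trait_name=trait_name, alphabet=alphabet, rate_matrix=q,
        log_likelihood=lnl, tree=work, marginals=marginals, root_prior=prior,
        converged=bool(res.success), model=model,
    )


def _updown(tree, tip_vec, q, prior):
    """Down (postorder conditionals) and out (preorder, indexed by the state
    at the parent end of each branch) vectors for marginals/sampling."""
    down, p_by_node = _postorder_conditionals(tree, tip_vec, q)
    out = {tree.seed_node: prior.copy()}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        messages = {c: p_by_node[c] @ down[c] for c in node.child_nodes()}
        for child in node.child_nodes():
            vec = out[node].copy()
            for sib in node.child_nodes():
                if sib is not child:
                    vec = vec * messages[sib]
            out[child] = vec
    return down, out, p_by_node


def _marginal_ancestral_states(tree, tip_states, alphabet, q, prior):
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    tip_vec = {}
    for taxon, state in tip_states.items():
        v = np.zeros(k)
        v[index[state]] = 1.0
        tip_vec[taxon] = v
    down, out, p_by_node = _updown(tree, tip_vec, q, prior)
    marginals = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            vec = prior * down[node]
        else:
            vec = (out[node] @ p_by_node[node]) * down[node]
        total = vec.sum()
        marginals[node] = vec / total if total > 0 else np.full(k, 1.0 / k)
    return marginals


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------

@dataclass
class BranchOccupancy:
    """Per-branch summaries over sampled histories.

    ``time_fraction[node][state]``: mean fraction of branch time in state;
    ``majority_fraction[node][state]``: fraction of maps in which the state
    occupies more than half of the branch. ``se`` gives the Monte-Carlo
    standard error of the time fraction.
    """

    alphabet: tuple
    n_maps: int
    seed: int
    time_fraction: dict
    majority_fraction: dict
    se: dict


def _sample_endpoint_conditioned_dwell(q, a, b, t, p_ab, rng, alphabet_size):
    """Dwell times of a CTMC path from state a to b over time t, sampled by
    uniformization (virtual jumps allowed)."""
    mu = float(np.max(-np.diag(q)))
    dwell = np.zeros(alphabet_size)
    if mu <= 0 or t <= 0:
        dwell[a] = max(t, 0.0)
        return dwell
    r = np.eye(alphabet_size) + q / mu
    # sample number of uniformized jumps
    u = rng.random()
    log_pois = -mu * t
    pois = np.exp(log_pois)
    rn = np.eye(alphabet_size)
    cum = 0.0
    n_jumps = None
    r_powers = [rn]
    for n in range(0, 200):
        if n > 0:
            pois *= mu * t / n
            r_powers.append(r_powers[-1] @ r)
        prob = pois * r_powers[n][a, b] / p_ab
        cum += prob
        if u <= cum:
            n_jumps = n
            break
    if n_jumps is None:  # numerical tail; fall back to the mode region
        n_jumps = max(1, int(mu * t))
        while len(r_powers) <= n_jumps:
            r_powers.append(r_powers[-1] @ r)
    if n_jumps == 0:
        dwell[a] = t
        return dwell
    # jump chain states via bridge sampling, then uniform order-statistic times
    states = [a]
    for m in range(1, n_jumps):
        back = r_powers[n_jumps - m]
        weights = r[states[-1], :] * back[:, b]
        total = weights.sum()
        if total <= 0:
            weights = np.full(alphabet_size, 1.0 / alphabet_size)
        else:
            weights = weights / total
        states.append(int(rng.choice(alphabet_size, p=weights)))
    states.append(b)
    times = np.sort(rng.random(n_jumps)) * t
    bounds = np.concatenate([[0.0], times, [t]])
    for seg_state, t0, t1 in zip(states, bounds[:-1], bounds[1:]):
        dwell[seg_state] += t1 - t0
    return dwell


def stochastic_maps(fit: MkFit, n_maps: int = 1000, seed: int = 0) -> BranchOccupancy:
    """Sample posterior trait histories and summarize per-branch occupancy.

    Node states are drawn from their joint posterior (downward sampling from
    the root), then each branch's path is sampled conditional on its endpoint
    states by uniformization. Reproducible under a fixed seed.
    """
    if n_maps < 1:
        raise ValidationError(f"n_maps must be >= 1, got {n_maps}")
    rng = np.random.default_rng(seed)
    tree, q, alphabet, prior = fit.tree, fit.rate_matrix, fit.alphabet, fit.root_prior
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    # tip states are delta distributions, recoverable from the fit marginals
    tip_vec = {node.taxon.label: fit.marginals[node].copy()
               for node in tree.leaf_node_iter()}
    down, _, p_by_node = _updown(tree, tip_vec, q, prior)
    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    dwell_sum = {n: np.zeros(k) for n in nodes}
    dwell_sq = {n: np.zeros(k) for n in nodes}
    majority = {n: np.zeros(k) for n in nodes}
    root = tree.seed_node
    root_post = prior * down[root]
    root_post = root_post / root_post.sum()
    for _ in range(n_maps):
        state_at = {root: int(rng.choice(k, p=root_post))}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            parent_state = state_at[node.parent_node]
            p = p_by_node[node]
            w = p[parent_state, :] * down[node]
            w = w / w.sum()
            state_at[node] = int(rng.choice(k, p=w))
        for node in nodes:
            t = node.edge.length or 0.0
            a, b = state_at[node.parent_node], state_at[node]
            if t <= 0:
                frac = np.zeros(k)
                frac[b] = 1.0
            else:
                p_ab = p_by_node[node][a, b]
                dwell = _sample_endpoint_conditioned_dwell(q, a, b, t, p_ab, rng, k)
                frac = dwell / t
            dwell_sum[node] += frac
            dwell_sq[node] += frac ** 2
            majority[node][int(np.argmax(frac))] += 1.0
    time_fraction, majority_fraction, se = {}, {}, {}
    for node in nodes:
        mean = dwell_sum[node] / n_maps
        var = dwell_sq[node] / n_maps - mean ** 2
        time_fraction[node] = {s: float(mean[i]) for i, s in enumerate(alphabet)}
        majority_fraction[node] = {s: float(majority[node][i] / n_maps)
                                   for i, s in enumerate(alphabet)}
        se[node] = {s: float(np.sqrt(max(var[i], 0.0) / n_maps))
                    for i, s in enumerate(alphabet)}
    return BranchOccupancy(alphabet=alphabet, n_maps=n_maps, seed=seed,
                           time_fraction=time_fraction,
                           majority_fraction=majority_fraction, se=se)


# ---------------------------------------------------------------------------
# Branch labeling
# ---------------------------------------------------------------------------

class AmbiguousLabelingError(ValueError):
    """Some branches fall below the occupancy threshold."""


def label_branches(tree: dendropy.Tree, occupancy: BranchOccupancy,
                   rule: str = "majority", tau: float | None = None,
                   force: bool = False) -> LabeledTree:
    """Collapse branch-state occupancies into one label per branch.

    ``majority``: highest time-fraction state wins; ties are broken toward
    the parent branch's label, then alphabetically. ``threshold``: branches
    whose top state has occupancy < tau are flagged ambiguous and the run
    aborts unless ``force`` (which then applies the majority rule to them).
    """
    if rule not in ("majority", "threshold"):
        raise ValidationError(f"unknown labeling rule {rule!r}")
    if rule == "threshold" and tau is None:
        raise ValidationError("threshold rule needs tau")
    alphabet = occupancy.alphabet
    labels: dict = {}
    ambiguous = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node not in occupancy.time_fraction:
            raise ValidationError("occupancy does not cover every branch")
        frac = occupancy.time_fraction[node]
        best = max(frac.values())
        top = sorted(s for s in alphabet if frac[s] == best)
        if rule == "threshold" and best < tau:
            ambiguous.append(node)
        if len(top) == 1:
            labels[node] = top[0]
        else:
            parent = node.parent_node
            parent_label = labels.get(parent)
            labels[node] = parent_label if parent_label in top else top[0]
    if ambiguous and not force:
        raise AmbiguousLabelingError(
            f"{len(ambiguous)} branch(es) below occupancy threshold {tau}"
        )
    return attach_labels(tree, labels, alphabet)


def label_from_tip_states(tree: dendropy.Tree, tip_states: dict,
                          alphabet=None) -> "BranchOccupancy":
    """Occupancies from a parsimony-style downpass/uppass (Fitch sets with
    the tie rules of :func:`label_branches`); useful for direct labeling when
    ancestral states are externally given or unambiguous."""
    if alphabet is None:
        alphabet = tuple(sorted(set(tip_states.values())))
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = {tip_states[node.taxon.label]}
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            inter = set.intersection(*child_sets)
            sets[node] = inter if inter else set.union(*child_sets)
    time_fraction = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = sets[node]
        time_fraction[node] = {a: (1.0 / len(s) if a in s else 0.0) for a in alphabet}
    return BranchOccupancy(alphabet=tuple(alphabet), n_maps=0, seed=0,
                           time_fraction=time_fraction,
                           majority_fraction=time_fraction, se={})


def _bipartition_key(node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def combine_labels(a: LabeledTree, b: LabeledTree, allowed_pairs: dict) -> LabeledTree:
    """Concatenate two labelings of the same topology into combined categories.

    ``allowed_pairs`` maps (label_a, label_b) -> combined category, e.g.
    {("U","H"): "UH", ("M","H"): "MH", ("M","HD"): "MHD"}. Branches whose
    observed pair is not allowed raise a validation error listing them.
    """
    keys_a = {_bipartition_key(n): n for n in a.tree.preorder_node_iter()
              if n is not a.tree.seed_node}
    keys_b = {_bipartition_key(n): n for n in b.tree.preorder_node_iter()
              if n is not b.tree.seed_node}
    if set(keys_a) != set(keys_b):
        raise ValidationError("trees do not share the same topology")
    work = a.copy()
    offending, labels = [], {}
    for node in work.tree.preorder_node_iter():
        if node is work.tree.seed_node:
            continue
        key = _bipartition_key(node)
        pair = (keys_a[key].category, keys_b[key].category)
        if pair not in allowed_pairs:
            offending.append((sorted(key)[0] if len(key) == 1 else f"clade{{{','.join(sorted(key))}}}", pair))
        else:
            labels[node] = allowed_pairs[pair]
    if offending:
        raise ValidationError(f"branch label pairs outside allowed alphabet: {offending}")
    alphabet = tuple(sorted(set(allowed_pairs.values())))
    return attach_labels(work.tree, labels, alphabet)
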