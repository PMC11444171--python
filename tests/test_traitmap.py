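"""Mk-model fitting, ancestral marginals, stochastic maps, branch labels."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phylosel.seqio import ValidationError, tree_from_string
from phylosel.traitmap import (
    BranchOccupancy,
    DegenerateTraitError,
    MkFit,
    _marginal_ancestral_states,
    combine_labels,
    fit_mk,
    label_branches,
    label_from_tip_states,
    mk_log_likelihood,
    stochastic_maps,
)

TREE4 = "((A:0.3,B:0.5):0.2,(C:0.4,D:0.6):0.3);"


def brute_force_likelihood_and_root_marginal(tree, tips, alphabet, q, prior):
    """Enumerate all internal-node state assignments explicitly."""
    k = len(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    p_edge = {n: expm(q * (n.edge.length or 0.0))
              for n in tree.preorder_node_iter() if n is not tree.seed_node}
    total = 0.0
    root_mass = np.zeros(k)
    for assign in itertools.product(range(k), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for leaf in tree.leaf_node_iter():
            states[leaf] = idx[tips[leaf.taxon.label]]
        lik = prior[states[tree.seed_node]]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            lik *= p_edge[node][states[node.parent_node], states[node]]
        total += lik
        root_mass[states[tree.seed_node]] += lik
    return np.log(total), root_mass / total


class TestMkLikelihood:
    def test_pruning_matches_enumeration(self):
        tree = tree_from_string(TREE4)
        tips = {"A": "x", "B": "y", "C": "x", "D": "y"}
        q = np.array([[-0.7, 0.7], [1.1, -1.1]])
        prior = np.array([1.1 / 1.8, 0.7 / 1.8])  # stationary of q
        lnl = mk_log_likelihood(tree, tips, ("x", "y"), q, prior)
        lnl_bf, root_bf = brute_force_likelihood_and_root_marginal(
            tree, tips, ("x", "y"), q, prior)
        assert lnl == pytest.approx(lnl_bf, abs=1e-8)
        marg = _marginal_ancestral_states(
            tree, tips, ("x", "y"),
            q, prior)
        assert marg[tree.seed_node] == pytest.approx(root_bf, abs=1e-9)

    def test_marginals_sum_to_one_everywhere(self):
        tree = tree_from_string(TREE4)
        fit = fit_mk(tree, {"A": "x", "B": "y", "C": "x", "D": "y"})
        for vec in fit.marginals.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_low_rate_limit_concentrates_on_majority_state(self):
        # one derived tip, rate -> 0: the root marginal approaches the
        # majority (ancestral) state
        tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": "x", "B": "x", "C": "x", "D": "y"}
        q = np.array([[-1e-4, 1e-4], [1e-4, -1e-4]])
        marg = _marginal_ancestral_states(tree, tips, ("x", "y"), q,
                                          np.array([0.5, 0.5]))
        assert marg[tree.seed_node][0] > 0.99

    def test_constant_trait_raises(self):
        tree = tree_from_string(TREE4)
        with pytest.raises(DegenerateTraitError):
            fit_mk(tree, {"A": "U", "B": "U", "C": "U", "D": "U"})

    def test_missing_tips_pruned_first(self):
        tree = tree_from_string("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        fit = fit_mk(tree, {"A": "x", "B": "y", "C": None, "D": "x", "E": "y"})
        kept = sorted(l.taxon.label for l in fit.tree.leaf_node_iter())
        assert kept == ["A", "B", "D", "E"]


class TestStochasticMaps:
    def _fit(self):
        tree = tree_from_string(TREE4)
        return fit_mk(tree, {"A": "x", "B": "y", "C": "x", "D": "y"})

    def test_same_seed_identical(self):
        fit = self._fit()
        occ1 = stochastic_maps(fit, n_maps=200, seed=42)
        occ2 = stochastic_maps(fit, n_maps=200, seed=42)
        for node in occ1.time_fraction:
            assert occ1.time_fraction[node] == occ2.time_fraction[node]

    def test_invalid_n_maps(self):
        with pytest.raises(ValidationError):
            stochastic_maps(self._fit(), n_maps=0)

    def test_constant_posterior_gives_full_occupancy(self):
        # near-zero rate + constant tips: every branch sits in that state
        tree = tree_from_string(TREE4)
        tips = {"A": "x", "B": "x", "C": "x", "D": "x"}
        q = np.array([[-1e-8, 1e-8], [1e-8, -1e-8]])
        marg = _marginal_ancestral_states(tree, tips, ("x", "y"), q,
                                          np.array([0.5, 0.5]))
        fit = MkFit(trait_name="t", alphabet=("x", "y"), rate_matrix=q,
                    log_likelihood=0.0, tree=tree, marginals=marg,
                    root_prior=np.array([0.5, 0.5]))
        occ = stochastic_maps(fit, n_maps=50, seed=1)
        for node in occ.time_fraction:
            assert occ.time_fraction[node]["x"] == pytest.approx(1.0, abs=1e-6)

    def test_mean_dwell_time_is_plausible(self):
        fit = self._fit()
        occ = stochastic_maps(fit, n_maps=500, seed=7)
        for node, frac in occ.time_fraction.items():
            assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)


class TestLabeling:
    def test_full_occupancy_labels_everything(self):
        tree = tree_from_string(TREE4)
        occ_tf = {n: {"U": 1.0, "M": 0.0} for n in tree.preorder_node_iter()
                  if n is not tree.seed_node}
        occ = BranchOccupancy(alphabet=("M", "U"), n_maps=1, seed=0,
                              time_fraction=occ_tf, majority_fraction=occ_tf,
                              se={})
        lt = label_branches(tree, occ)
        assert all(n.category == "U" for n in lt.tree.preorder_node_iter()
                   if n is not lt.tree.seed_node)

    def test_tie_breaks_toward_parent_label(self):
        tree = tree_from_string("((A:1,B:1):1,C:1);")
        nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
        occ_tf = {}
        for n in nodes:
            if n.is_leaf() and n.taxon.label == "A":
                occ_tf[n] = {"H": 0.5, "HD": 0.5}  # the tied branch
            else:
                occ_tf[n] = {"H": 1.0, "HD": 0.0}
        occ = BranchOccupancy(alphabet=("H", "HD"), n_maps=1, seed=0,
                              time_fraction=occ_tf, majority_fraction=occ_tf,
                              se={})
        lt = label_branches(tree, occ)
        label_a = next(n.category for n in lt.tree.leaf_node_iter()
                       if n.taxon.label == "A")
        assert label_a == "H"

    def test_reproduces_fitch_parsimony_on_hand_checked_tree(self):
        tree = tree_from_string("((A:1,B:1):1,((C:1,D:1):1,E:1):1);")
        tips = {"A": "U", "B": "U", "C": "M", "D": "M", "E": "M"}
        occ = label_from_tip_states(tree, tips)
        lt = label_branches(tree, occ)
        got = {}
        for n in lt.tree.preorder_node_iter():
            if n is lt.tree.seed_node:
                continue
            key = frozenset(l.taxon.label for l in n.leaf_iter())
            got[key] = n.category
        assert got[frozenset("AB")] == "U"
        assert got[frozenset("CD")] == "M"
        assert got[frozenset("CDE")] == "M"
        for tip, state in tips.items():
            assert got[frozenset(tip)] == state

    def test_labeling_invariant_to_taxon_input_order(self):
        tree = tree_from_string(TREE4)
        tips = {"A": "x", "B": "y", "C": "x", "D": "y"}
        occ_a = label_from_tip_states(tree, tips)
        occ_b = label_from_tip_states(tree, dict(reversed(list(tips.items()))))
        lt_a = label_branches(tree, occ_a)
        lt_b = label_branches(tree, occ_b)
        key = lambda lt: {frozenset(l.taxon.label for l in n.leaf_iter()): n.category
                          for n in lt.tree.preorder_node_iter()
                          if n is not lt.tree.seed_node}
        assert key(lt_a) == key(lt_b)


class TestCombineLabels:
    PAIRS = {("U", "H"): "UH", ("M", "H"): "MH", ("M", "HD"): "MHD"}

    def _labeled(self, newick, tips_to_label, default):
        tree = tree_from_string(newick)
        occ_tf = {}
        for n in tree.preorder_node_iter():
            if n is tree.seed_node:
                continue
            label = default
            if n.is_leaf() and n.taxon.label in tips_to_label:
                label = tips_to_label[n.taxon.label]
            states = sorted({label, default})
            occ_tf[n] = {s: (1.0 if s == label else 0.0) for s in states}
        alphabet = tuple(sorted({default, *tips_to_label.values()}))
        occ = BranchOccupancy(alphabet=alphabet, n_maps=1, seed=0,
                              time_fraction={
                                  n: {a: f.get(a, 0.0) for a in alphabet}
                                  for n, f in occ_tf.items()},
                              majority_fraction={}, se={})
        return label_branches(tree, occ)

    def test_all_u_times_all_h(self):
        a = self._labeled(TREE4, {}, "U")
        b = self._labeled(TREE4, {}, "H")
        combined = combine_labels(a, b, self.PAIRS)
        assert all(n.category == "UH" for n in combined.tree.preorder_node_iter()
                   if n is not combined.tree.seed_node)

    def test_m_branches_map_to_mh_and_mhd(self):
        a = self._labeled(TREE4, {}, "M")
        b = self._labeled(TREE4, {"A": "HD"}, "H")
        combined = combine_labels(a, b, self.PAIRS)
        cats = {n.taxon.label: n.category for n in combined.tree.leaf_node_iter()}
        assert cats["A"] == "MHD" and cats["B"] == "MH"

    def test_disallowed_pair_rejected(self):
        a = self._labeled(TREE4, {"A": "Sp"}, "U")
        b = self._labeled(TREE4, {}, "H")
        with pytest.raises(ValidationError, match="outside allowed"):
            combine_labels(a, b, self.PAIRS)
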