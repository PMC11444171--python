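"""GY94 branch-category model: rate matrix, likelihood, gradient, fitting."""

import numpy as np
import pytest

from phylosel.codonmodel import (
    CategoryAbsentError,
    CodonModelParams,
    FitConfig,
    LikelihoodEngine,
    _Eig,
    build_rate_matrix,
    collapse_to_single_category,
    count_sites,
    decompose_dn_ds,
    f3x4_frequencies,
    fit_branch_model,
    log_likelihood,
    syn_flux_fraction,
)
from phylosel.seqio import (
    CodonAlignment,
    ValidationError,
    attach_labels,
    tree_from_string,
)
from phylosel.simulate import simulate_codon_alignment

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def single_cat_ltree(newick, label="X"):
    tree = tree_from_string(newick)
    labels = {n: label for n in tree.preorder_node_iter()
              if n is not tree.seed_node}
    return attach_labels(tree, labels, (label,))


def two_cat_ltree(newick, cats):
    """cats: {tip label or frozenset of descendant tips: category}."""
    tree = tree_from_string(newick)
    labels = {}
    for n in tree.preorder_node_iter():
        if n is tree.seed_node:
            continue
        key = frozenset(l.taxon.label for l in n.leaf_iter())
        labels[n] = cats[key]
    return attach_labels(tree, labels, tuple(sorted(set(cats.values()))))


class TestRateMatrix:
    def test_detailed_balance(self, code1, uniform_pi):
        q = build_rate_matrix(1.0, 1.0, uniform_pi, code1)
        flux = uniform_pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_omega_zero_kills_nonsynonymous_entries(self, code1, uniform_pi):
        q = build_rate_matrix(2.0, 0.0, uniform_pi, code1)
        sense = code1.sense_codons
        for i in range(len(sense)):
            for j in range(len(sense)):
                if i == j:
                    continue
                diff = [(a, b) for a, b in zip(sense[i], sense[j]) if a != b]
                if len(diff) == 1 and code1.codon_to_aa[sense[i]] != code1.codon_to_aa[sense[j]]:
                    assert q[i, j] == 0.0

    def test_scaled_to_unit_rate(self, code1, uniform_pi):
        for kappa, omega in [(1.0, 1.0), (3.0, 0.1), (0.5, 2.0)]:
            q = build_rate_matrix(kappa, omega, uniform_pi, code1)
            assert -float(uniform_pi @ np.diag(q)) == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_nonpositive_pi_rejected(self, code1, uniform_pi):
        bad = uniform_pi.copy()
        bad[0] = 0.0
        bad[1] += 1 / 61
        with pytest.raises(ValidationError):
            build_rate_matrix(2.0, 0.5, bad, code1)


class TestFrequencies:
    def test_uniform_nucleotides_give_uniform_sense_pi(self, code1):
        # every nucleotide equally frequent at every position
        seq = "".join(code1.sense_codons) + "".join(code1.stop_codons)
        aln = CodonAlignment("g", ("A",), {"A": seq}, code1, len(seq) // 3)
        pi = f3x4_frequencies(aln)
        assert np.allclose(pi, 1.0 / 61, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_single_codon_concentrates_but_not_degenerate(self, code1):
        aln = CodonAlignment("g", ("A", "B"), {"A": "ATGATG", "B": "ATGATG"},
                             code1, 2)
        pi = f3x4_frequencies(aln)
        atg = code1.codon_index["ATG"]
        assert pi[atg] > 0.9
        assert pi[atg] < 1.0  # flooring keeps other codons possible
        assert np.all(pi > 0)


class TestCountSites:
    def test_matches_mutation_enumeration(self, code1, uniform_pi):
        # independent oracle: enumerate all single-nucleotide mutations of
        # all sense codons with kappa = 1 and uniform composition
        n_syn = n_tot = 0
        for codon in code1.sense_codons:
            for pos in range(3):
                for nuc in "ACGT":
                    if nuc == codon[pos]:
                        continue
                    mut = codon[:pos] + nuc + codon[pos + 1:]
                    if code1.codon_to_aa[mut] == "*":
                        continue
                    n_tot += 1
                    if code1.codon_to_aa[mut] == code1.codon_to_aa[codon]:
                        n_syn += 1
        s, n = count_sites(uniform_pi, 1.0, code1)
        assert s / 3.0 == pytest.approx(n_syn / n_tot, abs=1e-12)
        assert s / 3.0 == pytest.approx(0.24, abs=0.02)

    def test_transition_bias_raises_synonymous_fraction(self, code1, uniform_pi):
        s1, _ = count_sites(uniform_pi, 1.0, code1)
        s10, _ = count_sites(uniform_pi, 10.0, code1)
        assert s10 > s1

    def test_sites_sum_to_three(self, code1, uniform_pi):
        for kappa in (0.5, 1.0, 5.0):
            s, n = count_sites(uniform_pi, kappa, code1)
            assert s + n == pytest.approx(3.0, abs=1e-12)


class TestLikelihood:
    def test_two_taxon_closed_form(self, code1, uniform_pi):
        lt = single_cat_ltree("(A:0.1,B:0.25);")
        params = CodonModelParams(2.0, {"X": 0.3}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 40, seed=7, code=code1)
        lnl = log_likelihood(aln, lt, params)
        q = build_rate_matrix(2.0, 0.3, uniform_pi, code1)
        p = _Eig(q, uniform_pi).transition(0.35)
        idx = code1.codon_index
        direct = sum(np.log(uniform_pi[idx[a]] * p[idx[a], idx[b]])
                     for a, b in zip(aln.codons("A"), aln.codons("B")))
        assert lnl == pytest.approx(direct, abs=1e-8)

    def test_zero_branch_identical_sequences(self, code1, uniform_pi):
        seq = "ATGGCTAAACAT"
        aln = CodonAlignment("g", ("A", "B", "C"),
                             {t: seq for t in "ABC"}, code1, 4)
        lt = single_cat_ltree("(A:0,B:0,C:0);")
        params = CodonModelParams(2.0, {"X": 0.3}, uniform_pi)
        lnl = log_likelihood(aln, lt, params)
        expected = 4 * np.log(1 / 61)
        assert lnl == pytest.approx(expected, abs=1e-8)

    def test_label_structure_irrelevant_when_omegas_equal(self, code1, uniform_pi):
        newick = "((A:0.2,B:0.3):0.1,(C:0.15,D:0.4):0.2);"
        cats = {frozenset("A"): "P", frozenset("B"): "Q", frozenset("C"): "P",
                frozenset("D"): "Q", frozenset("AB"): "P", frozenset("CD"): "Q"}
        lt2 = two_cat_ltree(newick, cats)
        lt1 = single_cat_ltree(newick)
        params2 = CodonModelParams(2.0, {"P": 0.25, "Q": 0.25}, uniform_pi)
        params1 = CodonModelParams(2.0, {"X": 0.25}, uniform_pi)
        aln = simulate_codon_alignment(lt1, params1, 60, seed=9, code=code1)
        assert log_likelihood(aln, lt2, params2) == pytest.approx(
            log_likelihood(aln, lt1, params1), abs=1e-9)

    def test_root_placement_invariance(self, code1, uniform_pi):
        # same unrooted tree, two rootings (path lengths identical)
        lt_a = single_cat_ltree("((A:1,B:2):0.5,(C:3,D:4):0.7);")
        lt_b = single_cat_ltree("(A:0.5,(B:2,(C:3,D:4):1.2):0.5);")
        params = CodonModelParams(1.5, {"X": 0.4}, uniform_pi)
        aln = simulate_codon_alignment(lt_a, params, 50, seed=17, code=code1)
        assert log_likelihood(aln, lt_a, params) == pytest.approx(
            log_likelihood(aln, lt_b, params), abs=1e-6)

    def test_pruning_matches_brute_force_enumeration(self, code1, uniform_pi):
        # trifurcating root (unrooted parameterization): internal nodes are
        # the root and the AB ancestor
        newick = "((A:0.2,B:0.4):0.15,C:0.3,D:0.1);"
        cats = {frozenset("A"): "P", frozenset("B"): "P", frozenset("AB"): "P",
                frozenset("C"): "Q", frozenset("D"): "Q"}
        lt = two_cat_ltree(newick, cats)
        params = CodonModelParams(2.0, {"P": 0.1, "Q": 0.6}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 5, seed=3, code=code1)
        lnl = log_likelihood(aln, lt, params)

        # oracle: materialize the full joint over the two internal nodes
        qp = build_rate_matrix(2.0, 0.1, uniform_pi, code1)
        qq = build_rate_matrix(2.0, 0.6, uniform_pi, code1)
        pe = {"AB": _Eig(qp, uniform_pi).transition(0.15),
              "A": _Eig(qp, uniform_pi).transition(0.2),
              "B": _Eig(qp, uniform_pi).transition(0.4),
              "C": _Eig(qq, uniform_pi).transition(0.3),
              "D": _Eig(qq, uniform_pi).transition(0.1)}
        idx = code1.codon_index
        total = 0.0
        for site in range(5):
            a, b, c, d = (idx[aln.codons(t)[site]] for t in "ABCD")
            # T[r,u] = pi_r P_AB[r,u] P_A[u,a] P_B[u,b] P_C[r,c] P_D[r,d]
            tu = pe["A"][:, a] * pe["B"][:, b]
            joint = (uniform_pi[:, None] * pe["AB"]
                     * tu[None, :]
                     * (pe["C"][:, c] * pe["D"][:, d])[:, None])
            total += np.log(joint.sum())
        assert lnl == pytest.approx(total, abs=1e-8)

    def test_duplicated_columns_double_the_likelihood(self, code1, uniform_pi):
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);")
        params = CodonModelParams(2.0, {"X": 0.3}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 30, seed=5, code=code1)
        doubled = CodonAlignment(
            "g2", aln.taxa, {t: aln.sequences[t] * 2 for t in aln.taxa},
            code1, aln.n_codons * 2)
        assert log_likelihood(doubled, lt, params) == pytest.approx(
            2 * log_likelihood(aln, lt, params), rel=1e-12)

    def test_gap_codons_integrate_to_missing(self, code1, uniform_pi):
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);")
        params = CodonModelParams(2.0, {"X": 0.3}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 10, seed=5, code=code1)
        # masking one taxon's codon must give the likelihood of the reduced site
        seqs = dict(aln.sequences)
        seqs["C"] = "---" + seqs["C"][3:]
        masked = CodonAlignment("g", aln.taxa, seqs, code1, 10)
        lnl = log_likelihood(masked, lt, params)
        assert np.isfinite(lnl)
        assert lnl > log_likelihood(aln, lt, params) - 10  # sanity: close by


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, code1, uniform_pi):
        newick = "((A:0.2,B:0.4):0.15,(C:0.3,D:0.1):0.25);"
        cats = {frozenset("A"): "P", frozenset("B"): "P", frozenset("C"): "Q",
                frozenset("D"): "Q", frozenset("AB"): "P", frozenset("CD"): "Q"}
        lt = two_cat_ltree(newick, cats)
        params = CodonModelParams(2.0, {"P": 0.1, "Q": 0.6}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 80, seed=13, code=code1)
        eng = LikelihoodEngine(aln, lt, pi=uniform_pi)
        kappa, omegas, t = 1.7, np.array([0.15, 0.5]), eng.initial_lengths()
        _, grad = eng.log_likelihood_and_grad(kappa, omegas, t)
        x = np.log(np.concatenate([[kappa], omegas, t]))
        h = 1e-6
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            pp, pm = np.exp(xp), np.exp(xm)
            fd = (eng.log_likelihood(pp[0], pp[1:3], pp[3:])
                  - eng.log_likelihood(pm[0], pm[1:3], pm[3:])) / (2 * h)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestDecompose:
    def test_neutral_identity(self, code1, uniform_pi):
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);")
        params = CodonModelParams(2.0, {"X": 1.0}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 10, seed=5, code=code1)
        eng = LikelihoodEngine(aln, lt, pi=uniform_pi)
        lengths = eng.initial_lengths()
        est = decompose_dn_ds(eng, 2.0, np.array([1.0]), lengths)
        assert est["dN"]["X"] == pytest.approx(lengths.sum(), abs=1e-10)
        assert est["dS"]["X"] == pytest.approx(lengths.sum(), abs=1e-10)

    def test_matches_enumerated_flux_arithmetic(self, code1, uniform_pi):
        # independent oracle: enumerate the synonymous flux fraction from
        # the codon pair structure directly, then apply the definition
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);")
        params = CodonModelParams(2.0, {"X": 0.3}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 10, seed=5, code=code1)
        eng = LikelihoodEngine(aln, lt, pi=uniform_pi)
        lengths = eng.initial_lengths()
        kappa, omega = 2.0, 0.3
        syn = nonsyn = 0.0
        sense = code1.sense_codons
        for i, ci in enumerate(sense):
            for j, cj in enumerate(sense):
                if i == j:
                    continue
                diff = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diff) != 1:
                    continue
                is_ts = diff[0] in _TRANSITIONS
                is_syn = code1.codon_to_aa[ci] == code1.codon_to_aa[cj]
                w = uniform_pi[i] * uniform_pi[j] * (kappa if is_ts else 1.0) \
                    * (1.0 if is_syn else omega)
                if is_syn:
                    syn += w
                else:
                    nonsyn += w
        fs = syn / (syn + nonsyn)
        s_sites, n_sites = count_sites(uniform_pi, kappa, code1)
        t_tot = lengths.sum()
        est = decompose_dn_ds(eng, kappa, np.array([omega]), lengths)
        assert est["dS"]["X"] == pytest.approx(t_tot * fs / (s_sites / 3), abs=1e-10)
        assert est["dN"]["X"] == pytest.approx(
            t_tot * (1 - fs) / (n_sites / 3), abs=1e-10)
        assert fs == pytest.approx(
            syn_flux_fraction(kappa, omega, uniform_pi, code1), abs=1e-12)

    def test_highest_true_omega_category_ranks_highest(self, signal_battery):
        ok = sum(1 for est in signal_battery
                 if est.omega["B"] > est.omega["A"]
                 and est.dN["B"] / max(est.dS["B"], 1e-12)
                 > est.dN["A"] / max(est.dS["A"], 1e-12))
        assert ok / len(signal_battery) >= 0.95


class TestFit:
    def test_category_absent_raises(self, code1, uniform_pi):
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);", label="P")
        params = CodonModelParams(2.0, {"P": 0.3}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 10, seed=5, code=code1)
        bad = single_cat_ltree("((A:0.2,B:0.3):0.1,C:0.4);", label="P")
        bad.alphabet = ("P", "Q")  # declared category never realized
        with pytest.raises(CategoryAbsentError):
            fit_branch_model(aln, bad)

    def test_taxon_order_invariance(self, code1, uniform_pi, fast_fit):
        lt = single_cat_ltree("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.2);")
        params = CodonModelParams(2.0, {"X": 0.2}, uniform_pi)
        aln = simulate_codon_alignment(lt, params, 100, seed=19, code=code1)
        shuffled = CodonAlignment(aln.gene_id, tuple(reversed(aln.taxa)),
                                  aln.sequences, code1, aln.n_codons)
        e1 = fit_branch_model(aln, lt, fast_fit)
        e2 = fit_branch_model(shuffled, lt, fast_fit)
        assert e1.omega["X"] == pytest.approx(e2.omega["X"], abs=1e-6)
        assert e1.lnL == pytest.approx(e2.lnL, abs=1e-6)

    def test_omega_below_one_under_purifying_simulation(self, null_battery):
        # data simulated at omega = 0.2: the estimate stays below 1
        single_fits = [e1 for e1, _ in null_battery]
        frac = np.mean([e.omega["all"] < 1.0 for e in single_fits])
        assert frac >= 0.95

    def test_increasing_true_omega_increases_estimated_dn(
            self, code1, uniform_pi, fast_fit):
        # same tree and seeds; only category B's true omega moves
        from conftest import two_category_tree

        lt = two_category_tree(6, seed=51, height=0.8)
        mean_dn = {}
        for omega_b in (0.1, 0.4):
            vals = []
            for rep in range(10):
                params = CodonModelParams(
                    2.0, {"A": 0.15, "B": omega_b}, uniform_pi)
                aln = simulate_codon_alignment(lt, params, 100,
                                               seed=5000 + rep, code=code1)
                est = fit_branch_model(aln, lt, fast_fit)
                vals.append(est.dN["B"])
            mean_dn[omega_b] = np.mean(vals)
        assert mean_dn[0.4] > mean_dn[0.1]
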