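"""Shared fixtures: small trees, genetic codes and simulated batteries.

Expensive simulation+refit batteries are session-scoped so several tests
can share one run.
"""

import warnings

import numpy as np
import pytest

from phylosel.codonmodel import (
    CodonModelParams,
    FitConfig,
    collapse_to_single_category,
    fit_branch_model,
)
from phylosel.seqio import attach_labels, get_genetic_code, tree_from_string
from phylosel.simulate import (
    SimulationScenario,
    make_study_fixture,
    simulate_codon_alignment,
    simulate_tree,
)

warnings.filterwarnings("ignore", message="New seed_node has parent_node")


@pytest.fixture(scope="session")
def code1():
    return get_genetic_code(1)


@pytest.fixture(scope="session")
def code6():
    return get_genetic_code(6)


@pytest.fixture(scope="session")
def uniform_pi(code1):
    return np.full(code1.n_sense, 1.0 / code1.n_sense)


def two_category_tree(n_taxa, seed, height=0.8):
    """Birth-death tree with branches alternately labeled A/B (preorder)."""
    tree = simulate_tree(n_taxa, 1.0, 0.2, seed=seed, height=height)
    labels = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node is not tree.seed_node:
            labels[node] = "A" if i % 2 else "B"
    return attach_labels(tree, labels, ("A", "B"))


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """The default desk-scale synthetic study, written to disk once."""
    outdir = tmp_path_factory.mktemp("study")
    study = make_study_fixture(SimulationScenario(), outdir=outdir)
    study.outdir = outdir
    return study


@pytest.fixture(scope="session")
def null_battery(uniform_pi, code1):
    """50 data sets simulated with both categories sharing omega = 0.2,
    each refit under the single-ratio and the two-ratio model (the
    two-ratio fit warm-starts from the single-ratio solution, so the
    likelihood-ratio statistic is guaranteed non-negative). Sized at
    8 taxa x 300 codons, where the chi-square reference for the
    likelihood-ratio statistic is well calibrated."""
    ltree = two_category_tree(8, seed=21)
    single = collapse_to_single_category(ltree)
    params = CodonModelParams(kappa=2.0,
                              omega_by_category={"A": 0.2, "B": 0.2},
                              pi=uniform_pi)
    out = []
    for rep in range(50):
        aln = simulate_codon_alignment(ltree, params, 300, seed=1000 + rep,
                                       code=code1)
        e1 = fit_branch_model(aln, single, FitConfig(n_starts=1, seed=rep))
        e2 = fit_branch_model(aln, ltree, FitConfig(
            n_starts=1, seed=rep,
            init={"kappa": e1.kappa, "omegas": np.full(2, e1.omega["all"])}))
        out.append((e1, e2))
    return out


@pytest.fixture(scope="session")
def signal_battery(uniform_pi, code1):
    """25 data sets with a true omega contrast (A: 0.05, B: 0.3), refit with
    the two-ratio model; used for recovery and dN/dS ranking properties."""
    ltree = two_category_tree(6, seed=33)
    params = CodonModelParams(kappa=2.0,
                              omega_by_category={"A": 0.05, "B": 0.3},
                              pi=uniform_pi)
    out = []
    for rep in range(25):
        aln = simulate_codon_alignment(ltree, params, 200, seed=2000 + rep,
                                       code=code1)
        out.append(fit_branch_model(aln, ltree, FitConfig(n_starts=1, seed=rep)))
    return out


@pytest.fixture(scope="session")
def mini_study(tmp_path_factory):
    """A small, fast fixture for pipeline/CLI tests."""
    outdir = tmp_path_factory.mktemp("mini")
    scenario = SimulationScenario(n_taxa=10, n_genes=4, n_codons=120, seed=1,
                                  min_branches_per_category=1)
    study = make_study_fixture(scenario, outdir=outdir)
    study.outdir = outdir
    return study


@pytest.fixture()
def fast_fit():
    return FitConfig(n_starts=1, maxiter=300)
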