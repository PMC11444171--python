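"""Synthetic studies with known ground truth.

Generates birth-death species trees, discrete-trait histories (with the
empirically motivated coupling that haploid-diploid life cycles occur only
on multicellular branches), codon alignments evolved under branch-category
GY94 processes, and composition-null biased coding sequences. A "study
fixture" bundles many single-copy gene alignments over one shared species
tree with trait tables and model-specific labeled trees, mirroring the
structure of a multi-gene comparative selection analysis.

All randomness flows from one master seed; per-component substreams are
derived deterministically, so regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .codonmodel import CodonModelParams, _Eig, build_rate_matrix, _codon_pi_from_positional
from .seqio import (
    CodonAlignment,
    GeneticCode,
    LabeledTree,
    TraitTable,
    ValidationError,
    attach_labels,
    get_genetic_code,
    prune_labeled_tree,
    tree_from_string,
    tip_labels,
    write_codon_alignment,
    write_labeled_newick,
    write_newick,
    write_trait_table,
)


# ---------------------------------------------------------------------------
# Birth-death trees
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth: float = 1.0, death: float = 0.0,
                  seed: int = 0, height: float | None = 1.0,
                  max_attempts: int = 1000):
    """Ultrametric birth-death tree conditioned on ``n_taxa`` extant tips.

    Forward simulation from a single lineage, stopped right after the tip
    count first reaches ``n_taxa`` (cut before the next event); extinct
    lineages are pruned. Rescaled to total ``height`` if given.
    """
    if n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    if not birth > death or death < 0:
        raise ValidationError("need birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        newick = _forward_bd(n_taxa, birth, death, rng)
        if newick is not None:
            tree = tree_from_string(newick)
            if height is not None:
                _rescale_height(tree, height)
            return tree
    raise ValidationError(f"birth-death simulation failed after {max_attempts} attempts")


def _forward_bd(n_taxa, birth, death, rng):
    # node: [start_time, end_time|None, children list, alive flag]
    root = [0.0, None, [], True]
    active = [root]
    t = 0.0
    counter = [0]
    while True:
        n = len(active)
        if n == 0:
            return None  # clade extinct; retry
        rate = n * (birth + death)
        dt = rng.exponential(1.0 / rate)
        if n == n_taxa:
            t_stop = t + dt
            break
        t += dt
        lineage = active[rng.integers(n)]
        if rng.random() < birth / (birth + death):
            lineage[1] = t
            lineage[3] = False
            kids = [[t, None, [], True], [t, None, [], True]]
            lineage[2] = kids
            active.remove(lineage)
            active.extend(kids)
        else:
            lineage[1] = t
            lineage[3] = False
            active.remove(lineage)

    def render(node):
        start, end, children, alive = node
        if alive:
            counter[0] += 1
            return f"T{counter[0]:02d}:{t_stop - start:.12g}"
        parts = [render(c) for c in children]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            # extinct sibling: splice through, extending the child branch
            name, length = parts[0].rsplit(":", 1)
            return f"{name}:{float(length) + end - start:.12g}"
        return f"({','.join(parts)}):{end - start:.12g}"

    body = render(root)
    if body is None:
        return None
    # strip the root's own stem length
    name, _ = body.rsplit(":", 1)
    return name + ";"


def _tree_height(tree) -> float:
    def depth(node, acc):
        if node.is_leaf():
            return acc
        return max(depth(c, acc + (c.edge.length or 0.0)) for c in node.child_nodes())
    return depth(tree.seed_node, 0.0)


def _rescale_height(tree, height: float) -> None:
    h = _tree_height(tree)
    if h <= 0:
        raise ValidationError("zero-height tree cannot be rescaled")
    factor = height / h
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor


# ---------------------------------------------------------------------------
# Trait histories
# ---------------------------------------------------------------------------

def simulate_trait(tree, rate_matrix: np.ndarray, alphabet, root_state: str,
                   seed: int = 0):
    """Forward CTMC simulation of a discrete trait along the tree.

    Returns (tip_states, history) where history maps each non-root node to
    the list of (state, duration) segments along the branch above it,
    ordered from the parent end.
    """
    q = np.asarray(rate_matrix, float)
    alphabet = tuple(alphabet)
    k = len(alphabet)
    if q.shape != (k, k) or not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
        raise ValidationError("rate matrix rows must sum to 0 and match alphabet")
    index = {s: i for i, s in enumerate(alphabet)}
    rng = np.random.default_rng(seed)
    state_at = {tree.seed_node: index[root_state]}
    history: dict = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = state_at[node.parent_node]
        t_total = node.edge.length or 0.0
        segments = []
        elapsed = 0.0
        while True:
            out_rate = -q[s, s]
            wait = rng.exponential(1.0 / out_rate) if out_rate > 0 else np.inf
            if elapsed + wait >= t_total:
                segments.append((alphabet[s], t_total - elapsed))
                break
            segments.append((alphabet[s], wait))
            elapsed += wait
            probs = q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
        state_at[node] = s
        history[node] = segments
    tips = {leaf.taxon.label: alphabet[state_at[leaf]] for leaf in tree.leaf_node_iter()}
    return tips, history


def labels_from_history(tree, history: dict, alphabet,
                        project=None) -> LabeledTree:
    """True branch labels: the state occupying most of each branch's time
    (optionally projected, e.g. pair state -> body component)."""
    labels = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        dwell: dict = {}
        for state, dur in history[node]:
            s = project(state) if project else state
            dwell[s] = dwell.get(s, 0.0) + dur
        if not dwell:
            s = project(history[node][-1][0]) if project else history[node][-1][0]
            dwell[s] = 1.0
        best = max(dwell.values())
        labels[node] = sorted(s for s, d in dwell.items() if d == best)[0]
    return attach_labels(tree, labels, tuple(alphabet))


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(ltree: LabeledTree, params: CodonModelParams,
                             n_codons: int, seed: int = 0,
                             code: GeneticCode | None = None,
                             gene_id: str = "gene") -> CodonAlignment:
    """Evolve codons down a labeled tree under category-specific GY94 rates.

    Root codons are drawn from pi; each branch applies the transition matrix
    of its category at its own length (expected substitutions per codon).
    """
    code = code or get_genetic_code(1)
    pi = np.asarray(params.pi, float)
    rng = np.random.default_rng(seed)
    eigs = {c: _Eig(build_rate_matrix(params.kappa, w, pi, code), pi)
            for c, w in params.omega_by_category.items()}
    n_states = code.n_sense
    states = {ltree.tree.seed_node: rng.choice(n_states, size=n_codons, p=pi)}
    for node in ltree.tree.preorder_node_iter():
        if node is ltree.tree.seed_node:
            continue
        t = node.edge.length or 0.0
        p = eigs[node.category].transition(t)
        p = np.clip(p, 0.0, None)
        p = p / p.sum(axis=1, keepdims=True)
        parent = states[node.parent_node]
        child = np.empty(n_codons, dtype=int)
        for s in np.unique(parent):
            mask = parent == s
            child[mask] = rng.choice(n_states, size=int(mask.sum()), p=p[s])
        states[node] = child
    sense = code.sense_codons
    sequences = {}
    for leaf in ltree.tree.leaf_node_iter():
        sequences[leaf.taxon.label] = "".join(sense[i] for i in states[leaf])
    taxa = tuple(sorted(sequences))
    return CodonAlignment(gene_id=gene_id, taxa=taxa, sequences=sequences,
                          code=code, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Composition-null biased sequences
# ---------------------------------------------------------------------------

def generate_biased_sequence(gc3_target: float, n_codons: int,
                             code: GeneticCode | None = None,
                             seed: int = 0) -> str:
    """Coding sequence whose codon usage is driven purely by GC3.

    Amino acids are drawn uniformly over the degenerate families (family
    size >= 2); within a family the third-position G/C vs A/T class is
    chosen with probability ``gc3_target``, then uniformly within the class.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValidationError("gc3_target must be in (0, 1)")
    code = code or get_genetic_code(1)
    rng = np.random.default_rng(seed)
    families = []
    for aa, codons in sorted(code.aa_to_codons.items()):
        if len(codons) < 2:
            continue
        gc_side = tuple(c for c in codons if c[2] in "GC")
        at_side = tuple(c for c in codons if c[2] in "AT")
        families.append((gc_side, at_side))
    out = []
    fam_draw = rng.integers(len(families), size=n_codons)
    side_draw = rng.random(n_codons) < gc3_target
    for f, use_gc in zip(fam_draw, side_draw):
        gc_side, at_side = families[f]
        side = gc_side if (use_gc and gc_side) or not at_side else at_side
        out.append(side[rng.integers(len(side))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Study fixtures
# ---------------------------------------------------------------------------

# pair states couple life cycle to body architecture: HD occurs only on
# multicellular branches, as in the empirical trait distribution
PAIR_STATES = ("UH", "MH", "MHD", "SpH", "ScH")
_BODY = {"UH": "U", "MH": "M", "MHD": "M", "SpH": "Sp", "ScH": "Sc"}
_LIFE = {"UH": "H", "MH": "H", "MHD": "HD", "SpH": "H", "ScH": "H"}


def pair_rate_matrix(body_rate: float, lifecycle_rate: float) -> np.ndarray:
    """CTMC over coupled (body, life-cycle) states: equal-rates moves among
    body architectures within the haploid cycle, and H <-> HD switching on
    multicellular branches only."""
    k = len(PAIR_STATES)
    q = np.zeros((k, k))
    for i, a in enumerate(PAIR_STATES):
        for j, b in enumerate(PAIR_STATES):
            if i == j:
                continue
            if _LIFE[a] == _LIFE[b] == "H" and _BODY[a] != _BODY[b]:
                q[i, j] = body_rate
            elif _BODY[a] == _BODY[b] and _LIFE[a] != _LIFE[b]:
                q[i, j] = lifecycle_rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic data set.

    The desk-scale default (16 taxa x 20 genes x 300 codons) emulates the
    shape of a multi-gene comparative study over one species tree, with
    four body-architecture categories and two life-cycle categories, at a
    size a laptop test suite can refit end to end.
    """

    n_taxa: int = 16
    n_genes: int = 20
    n_codons: int = 300
    birth: float = 1.0
    death: float = 0.3
    tree_height: float = 1.0       # expected substitutions per codon, root to tip
    body_rate: float = 0.5
    lifecycle_rate: float = 0.8
    omega_by_category: dict = field(default_factory=lambda: {
        "U": 0.05, "M": 0.15, "Sp": 0.3, "Sc": 0.3})
    kappa: float = 2.0
    gc: float = 0.55               # nucleotide composition behind the codon pi
    gene_rate_sd: float = 0.3      # lognormal sd of per-gene rate multipliers
    lifecycle_missing_frac: float = 0.25
    gc3_targets: tuple = (0.3, 0.7)
    panel_codons: int = 3000
    min_branches_per_category: int = 2
    seed: int = 1


@dataclass
class SyntheticStudy:
    scenario: SimulationScenario
    species_tree: object
    ltree_m1: LabeledTree
    ltree_m2: LabeledTree
    ltree_m3: LabeledTree
    trait_table: TraitTable
    alignments: list
    truth: dict
    attempts: int


def _scenario_pi(scenario: SimulationScenario, code: GeneticCode) -> np.ndarray:
    gc = scenario.gc
    freqs = np.tile([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], (3, 1))
    return _codon_pi_from_positional(freqs, code)


def _category_branch_counts(ltree: LabeledTree) -> dict:
    counts: dict = {}
    for node in ltree.tree.preorder_node_iter():
        if node is ltree.tree.seed_node:
            continue
        counts[node.category] = counts.get(node.category, 0) + 1
    return counts


def realize_labeled_trees(scenario: SimulationScenario, max_attempts: int = 100):
    """Sample tree + coupled trait history until every model's categories are
    adequately represented; returns (tree, ltrees dict, tips, history, attempts)."""
    q = pair_rate_matrix(scenario.body_rate, scenario.lifecycle_rate)
    need_m1 = set(scenario.omega_by_category)
    for attempt in range(1, max_attempts + 1):
        tree = simulate_tree(scenario.n_taxa, scenario.birth, scenario.death,
                             seed=np.random.SeedSequence([scenario.seed, 11, attempt]).generate_state(1)[0] % (2**31),
                             height=scenario.tree_height)
        trait_seed = np.random.SeedSequence([scenario.seed, 13, attempt]).generate_state(1)[0] % (2**31)
        tips, history = simulate_trait(tree, q, PAIR_STATES, "UH", seed=trait_seed)
        try:
            m1 = labels_from_history(tree, history, ("M", "Sc", "Sp", "U"),
                                     project=lambda s: _BODY[s])
            m2 = labels_from_history(tree, history, ("H", "HD"),
                                     project=lambda s: _LIFE[s])
            pair = labels_from_history(tree, history, PAIR_STATES)
        except ValidationError:
            continue
        c1 = _category_branch_counts(m1)
        if set(c1) != need_m1 or min(c1.values()) < scenario.min_branches_per_category:
            continue
        c2 = _category_branch_counts(m2)
        if set(c2) != {"H", "HD"} or min(c2.values()) < scenario.min_branches_per_category:
            continue
        um_taxa = [t for t, s in tips.items() if _BODY[s] in ("U", "M")]
        if len(um_taxa) < 4:
            continue
        try:
            pair_pruned = prune_labeled_tree(pair, um_taxa)
        except ValidationError:
            continue
        c3 = _category_branch_counts(pair_pruned)
        if (set(c3) != {"UH", "MH", "MHD"}
                or min(c3.values()) < scenario.min_branches_per_category):
            continue
        m3 = LabeledTree(tree=pair_pruned.tree, alphabet=("MH", "MHD", "UH"))
        return tree, {"M1": m1, "M2": m2, "M3": m3}, tips, history, attempt
    raise ValidationError(
        f"could not realize all category constraints in {max_attempts} attempts")


def make_study_fixture(scenario: SimulationScenario | None = None,
                       outdir=None) -> SyntheticStudy:
    """Generate a full synthetic study; optionally write it as a directory
    tree (per-gene FASTA, labeled Newicks with sidecars, trait TSV,
    composition panel FASTA, ground-truth JSON)."""
    scenario = scenario or SimulationScenario()
    code = get_genetic_code(1)
    pi = _scenario_pi(scenario, code)
    tree, ltrees, tips, history, attempts = realize_labeled_trees(scenario)

    taxa = sorted(tips)
    trait_table = TraitTable(
        states={t: {"body_architecture": _BODY[tips[t]],
                    "life_cycle": _LIFE[tips[t]]} for t in taxa},
        alphabets={"body_architecture": ("M", "Sc", "Sp", "U"),
                   "life_cycle": ("H", "HD")},
    )
    # mask life-cycle state for a deterministic subset of taxa (emulating
    # species without published life-cycle information)
    rng_mask = np.random.default_rng([scenario.seed, 17])
    n_mask = int(round(scenario.lifecycle_missing_frac * len(taxa)))
    for t in rng_mask.permutation(taxa)[:n_mask]:
        trait_table.states[t]["life_cycle"] = None

    gene_rng = np.random.default_rng([scenario.seed, 19])
    gene_factors = np.exp(gene_rng.normal(0.0, scenario.gene_rate_sd,
                                          scenario.n_genes))
    alignments = []
    m1 = ltrees["M1"]
    base_lengths = {n: (n.edge.length or 0.0)
                    for n in m1.tree.preorder_node_iter()}
    for g in range(scenario.n_genes):
        gene_id = f"gene{g + 1:03d}"
        for n in m1.tree.preorder_node_iter():
            n.edge.length = base_lengths[n] * gene_factors[g]
        params = CodonModelParams(kappa=scenario.kappa,
                                  omega_by_category=dict(scenario.omega_by_category),
                                  pi=pi)
        aln = simulate_codon_alignment(
            m1, params, scenario.n_codons,
            seed=np.random.SeedSequence([scenario.seed, 23, g]).generate_state(1)[0] % (2**31),
            code=code, gene_id=gene_id)
        alignments.append(aln)
    for n in m1.tree.preorder_node_iter():
        n.edge.length = base_lengths[n]

    truth = {
        "scenario": asdict(scenario),
        "pi_gc": scenario.gc,
        "omega_by_category": dict(scenario.omega_by_category),
        "kappa": scenario.kappa,
        "gene_rate_factors": {f"gene{g + 1:03d}": float(f)
                              for g, f in enumerate(gene_factors)},
        "tip_pair_states": {t: tips[t] for t in taxa},
        "attempts": attempts,
    }

    study = SyntheticStudy(scenario=scenario, species_tree=tree,
                           ltree_m1=ltrees["M1"], ltree_m2=ltrees["M2"],
                           ltree_m3=ltrees["M3"], trait_table=trait_table,
                           alignments=alignments, truth=truth,
                           attempts=attempts)
    if outdir is not None:
        _write_study(study, Path(outdir))
    return study


def _write_study(study: SyntheticStudy, outdir: Path) -> None:
    scenario = study.scenario
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    write_newick(study.species_tree, outdir / "species_tree.nwk")
    write_labeled_newick(study.ltree_m1, outdir / "trees" / "M1.nwk")
    write_labeled_newick(study.ltree_m2, outdir / "trees" / "M2.nwk")
    write_labeled_newick(study.ltree_m3, outdir / "trees" / "M3.nwk")
    write_trait_table(study.trait_table, outdir / "traits.tsv")
    for aln in study.alignments:
        write_codon_alignment(aln, outdir / "genes" / f"{aln.gene_id}.fasta")
    code = get_genetic_code(1)
    taxa = sorted(study.trait_table.states)
    with open(outdir / "composition_panel.fasta", "w") as fh:
        for i, taxon in enumerate(taxa):
            target = scenario.gc3_targets[i % len(scenario.gc3_targets)]
            seq = generate_biased_sequence(
                target, scenario.panel_codons, code,
                seed=np.random.SeedSequence([scenario.seed, 29, i]).generate_state(1)[0] % (2**31))
            fh.write(f">{taxon}\n{seq}\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
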