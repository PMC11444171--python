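"""Readers, writers and tree utilities shared by all pipeline stages.

Handles in-frame codon alignments (FASTA), rooted phylogenies (Newick,
optionally with PAML-style ``#k`` branch marks), taxon-by-trait tables (TSV)
and genetic codes derived from the NCBI translation tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"
MISSING = None  # sentinel for missing trait states


class FrameError(ValueError):
    """Sequence length not divisible by three."""


class ValidationError(ValueError):
    """Input violates a structural contract."""


class InsufficientTaxaError(ValidationError):
    """Fewer taxa than an operation can work with."""


# ---------------------------------------------------------------------------
# Genetic codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with degeneracy structure recomputed from the codon table.

    ``degeneracy_classes`` maps synonymous-family size k to the amino acids
    whose family has exactly k sense codons; it is always derived from
    ``codon_to_aa``, never hard-coded, so alternate codes (e.g. NCBI table 6,
    where TAA/TAG encode Gln) get correct family sizes automatically.
    """

    code_id: int
    codon_to_aa: dict  # 64 codons -> one-letter aa or "*"
    sense_codons: tuple
    stop_codons: tuple
    aa_to_codons: dict = field(repr=False)
    degeneracy_classes: dict = field(repr=False)
    codon_index: dict = field(repr=False)  # sense codon -> position

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def translate(self, codon: str) -> str | None:
        """Amino acid for a codon, ``"*"`` for stop, None if ambiguous/gap."""
        return self.codon_to_aa.get(codon)


@lru_cache(maxsize=None)
def get_genetic_code(code_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from the NCBI translation table ``code_id``."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code_id]
    except KeyError as exc:
        raise ValidationError(f"unknown NCBI translation table: {code_id}") from exc
    codon_to_aa = {}
    for n1 in NUCLEOTIDES:
        for n2 in NUCLEOTIDES:
            for n3 in NUCLEOTIDES:
                codon = n1 + n2 + n3
                codon_to_aa[codon] = "*" if codon in table.stop_codons else table.forward_table[codon]
    sense = tuple(c for c in sorted(codon_to_aa) if codon_to_aa[c] != "*")
    stops = tuple(c for c in sorted(codon_to_aa) if codon_to_aa[c] == "*")
    aa_to_codons: dict = {}
    for codon in sense:
        aa_to_codons.setdefault(codon_to_aa[codon], []).append(codon)
    aa_to_codons = {aa: tuple(cs) for aa, cs in aa_to_codons.items()}
    classes: dict = {}
    for aa, cs in aa_to_codons.items():
        classes.setdefault(len(cs), []).append(aa)
    classes = {k: tuple(sorted(v)) for k, v in sorted(classes.items())}
    return GeneticCode(
        code_id=code_id,
        codon_to_aa=codon_to_aa,
        sense_codons=sense,
        stop_codons=stops,
        aa_to_codons=aa_to_codons,
        degeneracy_classes=classes,
        codon_index={c: i for i, c in enumerate(sense)},
    )


def split_codons(seq: str) -> list:
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def is_unambiguous(codon: str) -> bool:
    return all(n in NUCLEOTIDES for n in codon)


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame coding-sequence alignment over one gene.

    Gap codons (``---``) and codons containing ambiguity characters are
    treated as missing data throughout the package. In-frame stop codons are
    masked to gaps at read time (``n_masked_stops`` counts them).
    """

    gene_id: str
    taxa: tuple
    sequences: dict  # taxon -> codon string (upper case)
    code: GeneticCode
    n_codons: int
    n_masked_stops: int = 0

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"{self.gene_id}: duplicate taxa")
        for t in self.taxa:
            if not t:
                raise ValidationError(f"{self.gene_id}: empty taxon name")
            if len(self.sequences[t]) != 3 * self.n_codons:
                raise ValidationError(f"{self.gene_id}: ragged alignment at taxon {t!r}")

    def codons(self, taxon: str) -> list:
        return split_codons(self.sequences[taxon])

    def subset(self, keep) -> "CodonAlignment":
        keep = [t for t in self.taxa if t in set(keep)]
        return CodonAlignment(
            gene_id=self.gene_id,
            taxa=tuple(keep),
            sequences={t: self.sequences[t] for t in keep},
            code=self.code,
            n_codons=self.n_codons,
            n_masked_stops=self.n_masked_stops,
        )


def read_codon_alignment(path, code_id: int = 1, gene_id: str | None = None) -> CodonAlignment:
    """Read an in-frame FASTA codon alignment; mask internal stops to gaps."""
    path = Path(path)
    code = get_genetic_code(code_id)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    taxa, sequences = [], {}
    n_masked = 0
    n_codons = None
    for rec in records:
        name = rec.id
        if name in sequences:
            raise ValidationError(f"{path}: duplicate taxon {name!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise FrameError(f"{path}: sequence for {name!r} has length {len(seq)}, not divisible by 3")
        codons = split_codons(seq)
        if n_codons is None:
            n_codons = len(codons)
        elif len(codons) != n_codons:
            raise ValidationError(f"{path}: taxon {name!r} has {len(codons)} codons, expected {n_codons}")
        masked = []
        for c in codons:
            if is_unambiguous(c) and code.is_stop(c):
                masked.append(GAP_CODON)
                n_masked += 1
            else:
                masked.append(c)
        taxa.append(name)
        sequences[name] = "".join(masked)
    if n_masked:
        log.warning("%s: masked %d in-frame stop codon(s) to missing", path.name, n_masked)
    return CodonAlignment(
        gene_id=gene_id or path.stem,
        taxa=tuple(taxa),
        sequences=sequences,
        code=code,
        n_codons=n_codons,
        n_masked_stops=n_masked,
    )


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for t in aln.taxa:
            fh.write(f">{t}\n{aln.sequences[t]}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _validate_tree(tree: dendropy.Tree, source: str) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{source}: duplicate tip labels")
    n_defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_defaulted += 1
        elif edge.length < 0:
            raise ValidationError(f"{source}: negative branch length {edge.length}")
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    if n_defaulted:
        log.warning("%s: %d branch(es) had no length; defaulted to 0", source, n_defaulted)


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise ValidationError(f"Newick parse error: {exc}") from exc
    _validate_tree(tree, "newick")
    return tree


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; absent branch lengths default to 0 (warned)."""
    return tree_from_string(Path(path).read_text())


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_string(tree) + "\n")


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone_tree(tree: dendropy.Tree) -> dendropy.Tree:
    # round-trip through newick so the clone has independent nodes/taxa
    return tree_from_string(tree_to_string(tree))


def prune_to_taxa(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Prune a tree to ``keep``; degree-2 nodes are collapsed, lengths summed.

    Patristic distances among retained taxa are preserved exactly.
    """
    keep = set(keep)
    tips = set(tip_labels(tree))
    unknown = keep - tips
    if unknown:
        raise ValidationError(f"unknown taxa in keep set: {sorted(unknown)}")
    if len(keep) < 3:
        raise InsufficientTaxaError(f"need >= 3 taxa after pruning, got {len(keep)}")
    pruned = _clone_tree(tree)
    pruned.retain_taxa_with_labels(sorted(keep))
    pruned.purge_taxon_namespace()
    # dendropy sums edge lengths when suppressing unifurcations, but the root
    # may be left with a single child; absorb that stem into the child edge.
    root = pruned.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        child.parent_node = None
        pruned.seed_node = child
        pruned.seed_node.edge.length = 0.0
        root = pruned.seed_node
    _validate_tree(pruned, "pruned tree")
    return pruned


# ---------------------------------------------------------------------------
# Labeled trees (branch categories)
# ---------------------------------------------------------------------------

@dataclass
class LabeledTree:
    """A rooted tree in which every branch carries one category label.

    The label of the branch leading into node v is stored as ``v.category``
    (the root's own zero-length edge is unlabeled). ``alphabet`` is the
    ordered category alphabet, e.g. ("M", "Sc", "Sp", "U") for the
    body-architecture model.
    """

    tree: dendropy.Tree
    alphabet: tuple

    def __post_init__(self):
        self.alphabet = tuple(self.alphabet)
        seen = set()
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            cat = getattr(node, "category", None)
            if cat is None:
                raise ValidationError("unlabeled branch in LabeledTree")
            if cat not in self.alphabet:
                raise ValidationError(f"branch label {cat!r} outside alphabet {self.alphabet}")
            seen.add(cat)
        self.observed = tuple(sorted(seen))

    def categories_present(self) -> tuple:
        return self.observed

    def copy(self) -> "LabeledTree":
        newick, legend = labeled_tree_to_string(self)
        return labeled_tree_from_string(newick, legend)


def clone_with_node_map(tree: dendropy.Tree):
    """Independent structural clone plus an {old node: new node} mapping
    (via serialization; child order and hence traversal order is preserved)."""
    clone = tree_from_string(tree_to_string(tree))
    mapping = {}
    for old, new in zip(tree.postorder_node_iter(), clone.postorder_node_iter()):
        old_key = (frozenset(l.taxon.label for l in old.leaf_iter()))
        new_key = (frozenset(l.taxon.label for l in new.leaf_iter()))
        if old_key != new_key:
            raise ValidationError("tree clone traversal mismatch")
        mapping[old] = new
    return clone, mapping


def attach_labels(tree: dendropy.Tree, labels_by_node: dict, alphabet) -> LabeledTree:
    """Build a LabeledTree from ``{node: category}``; the input tree is left
    untouched (labels go onto an independent clone)."""
    clone, mapping = clone_with_node_map(tree)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        mapping[node].category = labels_by_node[node]
    return LabeledTree(tree=clone, alphabet=tuple(alphabet))


_MARK_AFTER_LEN = re.compile(r"([^,()\s:#]*)(:[0-9eE.+\-]+)\s*#\s*(\d+)")
_MARK_AFTER_NAME = re.compile(r"([^,()\s:#]+)\s*#\s*(\d+)")
_MARK_AFTER_PAREN = re.compile(r"\)\s*#\s*(\d+)")


def labeled_tree_from_string(newick: str, legend: dict | None = None) -> LabeledTree:
    """Parse a Newick string with PAML-style ``#k`` branch marks.

    ``legend`` maps mark number -> category name; without it the mark digits
    themselves are the categories.
    """
    s = _MARK_AFTER_LEN.sub(r"\1__MARK\3\2", newick)
    s = _MARK_AFTER_PAREN.sub(r")__MARK\1", s)
    s = _MARK_AFTER_NAME.sub(r"\1__MARK\2", s)
    tree = tree_from_string(s)
    marks = set()
    for node in tree.preorder_node_iter():
        label_holder = node.taxon if node.taxon is not None else node
        label = label_holder.label
        mark = None
        if label and "__MARK" in label:
            base, mark = label.rsplit("__MARK", 1)
            label_holder.label = base or None
        if node is tree.seed_node:
            continue
        if mark is None:
            raise ValidationError("labeled Newick has an unmarked branch")
        marks.add(int(mark))
        node.category = int(mark)
    if legend is None:
        legend = {m: str(m) for m in sorted(marks)}
    missing = marks - set(legend)
    if missing:
        raise ValidationError(f"marks without legend entry: {sorted(missing)}")
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node.category = legend[node.category]
    alphabet = tuple(sorted(set(legend.values())))
    return LabeledTree(tree=tree, alphabet=alphabet)


def labeled_tree_to_string(ltree: LabeledTree) -> tuple:
    """Serialize to (marked newick, legend dict mark->category)."""
    legend = {i: cat for i, cat in enumerate(ltree.alphabet)}
    cat_to_mark = {cat: i for i, cat in legend.items()}

    def render(node) -> str:
        if node.is_leaf():
            core = node.taxon.label
        else:
            core = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return core
        length = node.edge.length if node.edge.length is not None else 0.0
        return f"{core}:{length:.10g} #{cat_to_mark[node.category]}"

    return render(ltree.tree.seed_node) + ";", legend


def write_labeled_newick(ltree: LabeledTree, path) -> None:
    """Write marked Newick plus a sidecar ``<path>.labels.tsv`` legend."""
    path = Path(path)
    newick, legend = labeled_tree_to_string(ltree)
    path.write_text(newick + "\n")
    sidecar = path.with_suffix(path.suffix + ".labels.tsv")
    with open(sidecar, "w") as fh:
        fh.write("mark\tcategory\n")
        for mark, cat in sorted(legend.items()):
            fh.write(f"{mark}\t{cat}\n")


def read_labeled_newick(path) -> LabeledTree:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".labels.tsv")
    legend = None
    if sidecar.exists():
        legend = {}
        for line in sidecar.read_text().splitlines()[1:]:
            mark, cat = line.split("\t")
            legend[int(mark)] = cat
    return labeled_tree_from_string(path.read_text(), legend)


def prune_labeled_tree(ltree: LabeledTree, keep) -> LabeledTree:
    """Prune a labeled tree; a collapsed degree-2 node's merged branch takes
    the label of the longer of the two merged segments (tie -> child side)."""
    keep = set(keep)
    tips = set(tip_labels(ltree.tree))
    unknown = keep - tips
    if unknown:
        raise ValidationError(f"unknown taxa in keep set: {sorted(unknown)}")
    if len(keep) < 3:
        raise InsufficientTaxaError(f"need >= 3 taxa after pruning, got {len(keep)}")
    work = ltree.copy()
    tree = work.tree
    # iteratively drop unwanted leaves
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if leaf.taxon is not None and leaf.taxon.label in keep:
                continue
            parent = leaf.parent_node
            parent.remove_child(leaf)
            changed = True
    # collapse degree-2 internal nodes, merging lengths and labels
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_node_iter()):
            children = node.child_nodes()
            if node is tree.seed_node:
                if len(children) == 1:
                    child = children[0]
                    child.parent_node = None
                    tree.seed_node = child
                    child.edge.length = 0.0
                    changed = True
                continue
            if not node.is_leaf() and len(children) == 1:
                child = children[0]
                t_parent = node.edge.length or 0.0
                t_child = child.edge.length or 0.0
                if t_parent > t_child:
                    child.category = node.category
                parent = node.parent_node
                parent.remove_child(node)
                parent.add_child(child)
                child.edge.length = t_parent + t_child
                changed = True
    tree.purge_taxon_namespace()
    _validate_tree(tree, "pruned labeled tree")
    return LabeledTree(tree=tree, alphabet=ltree.alphabet)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "?"}


@dataclass
class TraitTable:
    """Taxon -> {trait -> state or None}; states validated against alphabets."""

    states: dict  # taxon -> {trait -> state|None}
    alphabets: dict  # trait -> tuple of allowed states

    def taxa(self) -> tuple:
        return tuple(self.states)

    def column(self, trait: str) -> dict:
        """Non-missing states for one trait: taxon -> state."""
        if trait not in self.alphabets:
            raise ValidationError(f"unknown trait {trait!r}")
        return {t: s[trait] for t, s in self.states.items() if s.get(trait) is not None}


def read_trait_table(path, trait_specs: dict) -> TraitTable:
    """Read a TSV with a taxon column plus one column per declared trait.

    ``trait_specs`` maps trait (column) name -> allowed state alphabet.
    Empty/NA cells are stored as missing and never imputed.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    taxon_col = df.columns[0]
    for trait in trait_specs:
        if trait not in df.columns:
            raise ValidationError(f"{path}: missing trait column {trait!r}")
    states: dict = {}
    for _, row in df.iterrows():
        taxon = row[taxon_col].strip()
        if not taxon:
            raise ValidationError(f"{path}: empty taxon name")
        if taxon in states:
            raise ValidationError(f"{path}: duplicate taxon {taxon!r}")
        entry = {}
        for trait, alphabet in trait_specs.items():
            raw = str(row[trait]).strip()
            if raw.lower() in _MISSING_TOKENS:
                entry[trait] = None
            elif raw in set(alphabet):
                entry[trait] = raw
            else:
                raise ValidationError(
                    f"{path}: state {raw!r} for taxon {taxon!r}, trait {trait!r} "
                    f"not in alphabet {tuple(alphabet)}"
                )
        states[taxon] = entry
    return TraitTable(states=states, alphabets={k: tuple(v) for k, v in trait_specs.items()})


def write_trait_table(table: TraitTable, path) -> None:
    traits = list(table.alphabets)
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(traits) + "\n")
        for taxon, entry in table.states.items():
            cells = [entry.get(tr) if entry.get(tr) is not None else "" for tr in traits]
            fh.write(taxon + "\t" + "\t".join(cells) + "\n")
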