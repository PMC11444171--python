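"""Orchestration: per-gene branch-model fits, codon-bias profiling and
category comparisons over a directory of gene alignments.

A run takes a directory of in-frame FASTA alignments, a labeled tree (or a
plain tree plus a trait table to estimate labels from), fits the
branch-category codon model gene by gene (pruning each gene's tree to the
taxa present, skipping genes that lose a whole category), and summarizes
the per-gene estimates with paired signed-rank comparisons. Every input
gene is accounted for exactly once in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codonbias import profile_sequence
from .codonmodel import (
    CategoryAbsentError,
    CategoryEstimates,
    FitConfig,
    fit_branch_model,
)
from .compare import build_gene_category_table, compare_categories, summarize, to_long_format
from .seqio import (
    InsufficientTaxaError,
    LabeledTree,
    ValidationError,
    get_genetic_code,
    prune_labeled_tree,
    read_codon_alignment,
    read_labeled_newick,
    read_newick,
    read_trait_table,
    tip_labels,
)
from .traitmap import fit_mk, label_branches, stochastic_maps

log = logging.getLogger(__name__)

MODEL_SPECS = {
    # model -> (trait column(s), category alphabet, comparison pairs with the
    # expected stronger-selection category first)
    "M1": (("body_architecture",), ("M", "Sc", "Sp", "U"),
           [("U", "M"), ("U", "Sp"), ("U", "Sc")]),
    "M2": (("life_cycle",), ("H", "HD"), [("H", "HD")]),
    "M3": (("body_architecture", "life_cycle"), ("MH", "MHD", "UH"),
           [("UH", "MH"), ("MH", "MHD")]),
}


@dataclass
class RunConfig:
    """Validated run configuration (constructed directly or from YAML)."""

    alignment_dir: str
    tree: str                       # labeled newick (with sidecar) or plain newick
    out_dir: str
    model: str = "M1"
    trait_table: str | None = None  # required when labels must be estimated
    lifecycle_mode: str = "conservative"  # or "liberal"
    taxon_exclusions: tuple = ()
    code_id: int = 1
    alt_code_taxa: tuple = ()       # taxa profiled under NCBI table 6
    alt_code_id: int = 6
    bias_mode: str = "concatenated"  # or "per-gene"
    n_maps: int = 1000
    seed: int = 1
    threads: int = 1
    fit: FitConfig = field(default_factory=FitConfig)

    def validate(self) -> None:
        if self.model not in MODEL_SPECS:
            raise ValidationError(f"unknown model {self.model!r}; choose from {sorted(MODEL_SPECS)}")
        if self.lifecycle_mode not in ("conservative", "liberal"):
            raise ValidationError("lifecycle_mode must be 'conservative' or 'liberal'")
        if self.bias_mode not in ("concatenated", "per-gene"):
            raise ValidationError("bias_mode must be 'concatenated' or 'per-gene'")
        if not Path(self.alignment_dir).is_dir():
            raise ValidationError(f"alignment_dir not found: {self.alignment_dir}")
        if not Path(self.tree).exists():
            raise ValidationError(f"tree not found: {self.tree}")
        if self.trait_table is not None and not Path(self.trait_table).exists():
            raise ValidationError(f"trait_table not found: {self.trait_table}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fit_raw = raw.pop("fit", {})
    cfg = RunConfig(**raw, fit=FitConfig(**fit_raw))
    cfg.validate()
    return cfg


def _gene_files(config: RunConfig) -> list:
    return sorted(Path(config.alignment_dir).glob("*.fasta"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Labeled tree acquisition
# ---------------------------------------------------------------------------

def resolve_labeled_tree(config: RunConfig) -> LabeledTree:
    """Use the supplied labeled tree if the Newick carries branch marks;
    otherwise estimate labels from the trait table by stochastic mapping."""
    text = Path(config.tree).read_text()
    if "#" in text:
        ltree = read_labeled_newick(config.tree)
        expected = set(MODEL_SPECS[config.model][1])
        if set(ltree.alphabet) != expected:
            raise ValidationError(
                f"labeled tree alphabet {ltree.alphabet} does not match model "
                f"{config.model} categories {sorted(expected)}")
        return ltree
    if config.trait_table is None:
        raise ValidationError(
            f"tree {config.tree} carries no branch labels and no trait_table "
            "was given to estimate them from")
    traits, alphabet, _ = MODEL_SPECS[config.model]
    if len(traits) != 1:
        raise ValidationError(
            "combined-trait labels must be supplied as a labeled tree "
            "(estimate the component traits separately and combine)")
    tree = read_newick(config.tree)
    table = read_trait_table(config.trait_table, _trait_specs(config))
    column = table.column(traits[0])
    fit = fit_mk(tree, column, trait_name=traits[0])
    occ = stochastic_maps(fit, n_maps=config.n_maps, seed=config.seed)
    return label_branches(fit.tree, occ)


def _trait_specs(config: RunConfig) -> dict:
    lc_states = ("D", "H", "HD") if config.lifecycle_mode == "liberal" else ("H", "HD")
    return {"body_architecture": ("M", "Sc", "Sp", "U"), "life_cycle": lc_states}


def lifecycle_exclusions(table, mode: str) -> set:
    """Taxa excluded by the life-cycle dataset mode.

    Conservative: taxa with unknown life cycle, the diploids, and the
    siphonous/siphonocladous body architectures (whose life-cycle
    interpretation is unreliable). Liberal: only taxa with unknown life
    cycle (diploids form their own category)."""
    out = set()
    for taxon, states in table.states.items():
        lc = states.get("life_cycle")
        body = states.get("body_architecture")
        if lc is None:
            out.add(taxon)
        elif mode == "conservative" and (lc == "D" or body in ("Sp", "Sc")):
            out.add(taxon)
    return out


# ---------------------------------------------------------------------------
# Selection analysis
# ---------------------------------------------------------------------------

def _fit_one_gene(args):
    path, ltree_newick, legend, config = args
    from .seqio import labeled_tree_from_string

    ltree = labeled_tree_from_string(ltree_newick, legend)
    gene_id = path.stem
    try:
        aln = read_codon_alignment(path, code_id=config.code_id)
        keep = sorted((set(aln.taxa) & set(tip_labels(ltree.tree)))
                      - set(config.taxon_exclusions))
        if len(keep) < 3:
            return gene_id, "skipped", f"only {len(keep)} usable taxa", None
        pruned = prune_labeled_tree(ltree, keep) if set(keep) != set(tip_labels(ltree.tree)) else ltree
        fit_cfg = dataclasses.replace(
            config.fit, seed=int(np.random.SeedSequence(
                [config.seed, abs(hash(gene_id)) % (2 ** 31)]).generate_state(1)[0] % (2 ** 31)))
        est = fit_branch_model(aln.subset(keep), pruned, fit_cfg)
        status = "ok" if est.converged else "ok-unconverged"
        return gene_id, status, "", est
    except CategoryAbsentError as exc:
        return gene_id, "skipped", str(exc), None
    except (ValidationError, InsufficientTaxaError) as exc:
        return gene_id, "skipped", str(exc), None
    except Exception as exc:  # any other stage failure: gene fails, run continues
        return gene_id, "failed", f"{type(exc).__name__}: {exc}", None


def run_selection_analysis(config: RunConfig) -> dict:
    """Fit the branch model for every gene, compare categories, write outputs.

    Returns {"estimates": [...], "comparisons": DataFrame, "manifest": dict}.
    """
    config.validate()
    from .seqio import labeled_tree_to_string

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ltree = resolve_labeled_tree(config)
    exclusions = set(config.taxon_exclusions)
    if config.model in ("M2", "M3") and config.trait_table is not None:
        table = read_trait_table(config.trait_table, _trait_specs(config))
        exclusions |= lifecycle_exclusions(table, config.lifecycle_mode)
    work_cfg = dataclasses.replace(config, taxon_exclusions=tuple(sorted(exclusions)))
    newick, legend = labeled_tree_to_string(ltree)
    files = _gene_files(config)
    if not files:
        raise ValidationError(f"no .fasta alignments in {config.alignment_dir}")
    jobs = [(p, newick, legend, work_cfg) for p in files]
    if config.threads > 1:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            raw = list(pool.map(_fit_one_gene, jobs))
    else:
        raw = [_fit_one_gene(j) for j in jobs]
    raw.sort(key=lambda r: r[0])

    estimates = [est for _, _, _, est in raw if est is not None]
    statuses = [{"gene_id": g, "status": s, "reason": r} for g, s, r, _ in raw]
    est_df = estimates_to_frame(estimates)
    est_path = out_dir / "estimates.tsv"
    est_df.to_csv(est_path, sep="\t", index=False, float_format="%.8g")

    pairs = MODEL_SPECS[config.model][2]
    comparisons = pd.DataFrame()
    summary = pd.DataFrame()
    if estimates:
        table = build_gene_category_table(estimates)
        comparisons = compare_categories(table, pairs)
        summary = summarize(table)
        to_long_format(table).to_csv(out_dir / "long_values.tsv", sep="\t",
                                     index=False, float_format="%.8g")
    cmp_path = out_dir / "comparisons.tsv"
    comparisons.to_csv(cmp_path, sep="\t", index=False, float_format="%.8g")
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False,
                   float_format="%.8g")

    manifest = {
        "version": __version__,
        "config": _config_echo(config),
        "seed": config.seed,
        "genes": statuses,
        "n_ok": sum(1 for s in statuses if s["status"].startswith("ok")),
        "n_skipped": sum(1 for s in statuses if s["status"] == "skipped"),
        "n_failed": sum(1 for s in statuses if s["status"] == "failed"),
        "inputs": {str(p): _sha256(p) for p in files},
        "outputs": {},
    }
    assert manifest["n_ok"] + manifest["n_skipped"] + manifest["n_failed"] == len(files)
    for p in (est_path, cmp_path):
        manifest["outputs"][str(p)] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"estimates": estimates, "comparisons": comparisons,
            "summary": summary, "manifest": manifest}


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["fit"] = dataclasses.asdict(config.fit)
    return echo


def estimates_to_frame(estimates: list) -> pd.DataFrame:
    rows = []
    for est in estimates:
        for cat in est.categories:
            rows.append({
                "gene_id": est.gene_id, "category": cat,
                "omega": est.omega[cat], "dN": est.dN[cat], "dS": est.dS[cat],
                "kappa": est.kappa, "lnL": est.lnL, "n_codons": est.n_codons,
                "converged": est.converged,
            })
    cols = ["gene_id", "category", "omega", "dN", "dS", "kappa", "lnL",
            "n_codons", "converged"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["gene_id", "category"]).reset_index(drop=True)


def compare_existing(estimates_tsv, model: str, out_path=None) -> pd.DataFrame:
    """Comparative statistics over a previously written estimates table."""
    df = pd.read_csv(estimates_tsv, sep="\t")
    ests = []
    for gene_id, sub in df.groupby("gene_id"):
        cats = tuple(sub["category"])
        ests.append(CategoryEstimates(
            gene_id=gene_id, categories=cats,
            omega=dict(zip(sub["category"], sub["omega"])),
            dN=dict(zip(sub["category"], sub["dN"])),
            dS=dict(zip(sub["category"], sub["dS"])),
            kappa=float(sub["kappa"].iloc[0]), lnL=float(sub["lnL"].iloc[0]),
            n_codons=int(sub["n_codons"].iloc[0]),
            converged=bool(sub["converged"].all()),
        ))
    table = build_gene_category_table(ests)
    comparisons = compare_categories(table, MODEL_SPECS[model][2])
    if out_path is not None:
        comparisons.to_csv(out_path, sep="\t", index=False, float_format="%.8g")
    return comparisons


# ---------------------------------------------------------------------------
# Codon-bias analysis
# ---------------------------------------------------------------------------

def run_codon_bias_analysis(config: RunConfig) -> pd.DataFrame:
    """Per-taxon (or per-taxon-per-gene) ENC/GC/GC3/EENC/DENC profiles.

    Taxa listed in ``alt_code_taxa`` are profiled under the alternate
    nuclear code (NCBI table 6 by default, where TAA/TAG encode Gln)."""
    config.validate()
    files = _gene_files(config)
    if not files:
        raise ValidationError(f"no .fasta alignments in {config.alignment_dir}")
    seqs: dict = {}
    order: dict = {}
    for path in files:
        aln = read_codon_alignment(path, code_id=config.code_id)
        for taxon in aln.taxa:
            seqs.setdefault(taxon, {})[aln.gene_id] = aln.sequences[taxon]
            order.setdefault(taxon, []).append(aln.gene_id)
    missing_alt = set(config.alt_code_taxa) - set(seqs)
    if missing_alt:
        log.warning("alt-code taxa absent from alignments: %s", sorted(missing_alt))
    rows = []
    for taxon in sorted(seqs):
        code = get_genetic_code(
            config.alt_code_id if taxon in set(config.alt_code_taxa) else config.code_id)
        if config.bias_mode == "concatenated":
            seq = "".join(seqs[taxon][g] for g in sorted(seqs[taxon]))
            rows.append(profile_sequence(seq, code, taxon))
        else:
            for gene_id in sorted(seqs[taxon]):
                rows.append(profile_sequence(seqs[taxon][gene_id], code, taxon, gene_id))
    df = pd.DataFrame([{
        "taxon": p.taxon, "gene_id": p.gene_id, "OENC": p.oenc,
        "OENC_raw": p.oenc_raw, "GC": p.gc, "GC3": p.gc3, "EENC": p.eenc,
        "DENC": p.denc, "gc_degenerate_46": p.gc_degenerate_46,
        "n_codons_used": p.n_codons_used,
    } for p in rows])
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "codon_bias.tsv", sep="\t", index=False,
              float_format="%.6g")
    return df


def validate_inputs(config: RunConfig) -> list:
    """Check inputs only; returns a list of problems (empty = valid)."""
    problems = []
    try:
        config.validate()
    except ValidationError as exc:
        return [str(exc)]
    try:
        ltree = resolve_labeled_tree(config)
        tips = set(tip_labels(ltree.tree))
    except ValidationError as exc:
        problems.append(f"tree: {exc}")
        tips = set()
    files = _gene_files(config)
    if not files:
        problems.append(f"no .fasta alignments in {config.alignment_dir}")
    for path in files:
        try:
            aln = read_codon_alignment(path, code_id=config.code_id)
            if tips and len(set(aln.taxa) & tips) < 3:
                problems.append(f"{path.name}: fewer than 3 taxa shared with tree")
        except (ValidationError, Exception) as exc:
            problems.append(f"{path.name}: {exc}")
    return problems
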