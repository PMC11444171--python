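"""Codon-usage-bias and nucleotide-composition metrics.

Implements Wright's effective number of codons (ENC), overall GC and
third-position GC (GC3), the GC3-driven null expectation for ENC (EENC),
their difference DENC = EENC - OENC, and GC usage at fully degenerate third
positions of 4- and 6-fold synonymous families.

A DENC near zero means the observed codon bias is no stronger than what the
sequence's nucleotide composition alone would produce; positive DENC points
to additional constraint (e.g. translational selection) on synonymous sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import (
    GAP_CODON,
    GeneticCode,
    NUCLEOTIDES,
    ValidationError,
    is_unambiguous,
    split_codons,
)

ENC_MIN = 20.0
ENC_MAX = 61.0


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given sequence (reason in message)."""


@dataclass
class CodonBiasProfile:
    """Per-taxon (or per-gene) codon-bias profile."""

    taxon: str
    gene_id: str  # "genome-wide" for concatenated profiles
    oenc: float | None
    oenc_raw: float | None  # before clamping to [20, 61]
    gc: float | None
    gc3: float | None
    eenc: float | None
    denc: float | None
    gc_degenerate_46: float | None
    n_codons_used: int


def usable_codons(seq: str) -> list:
    """In-frame codons with gaps and ambiguity-containing codons dropped."""
    return [c for c in split_codons(seq.upper().replace("U", "T"))
            if c != GAP_CODON and is_unambiguous(c)]


def codon_counts(seq: str, code: GeneticCode) -> dict:
    """Counts of sense codons grouped by amino acid; stops excluded."""
    out: dict = {}
    n = 0
    for codon in usable_codons(seq):
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        out.setdefault(aa, {}).setdefault(codon, 0)
        out[aa][codon] += 1
        n += 1
    if n == 0:
        raise UndefinedMetricError("no usable sense codons in sequence")
    return out


def _family_homozygosity(counts: dict) -> float | None:
    """Wright's F-hat for one synonymous family; None when n < 2."""
    n = sum(counts.values())
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: dict, code: GeneticCode, clamp: bool = True) -> float:
    """Wright's effective number of codons from a per-amino-acid count table.

    Family-size classes come from the genetic code (so alternate codes get
    their own class structure). Per class the mean F-hat is taken over amino
    acids with usage >= 2; amino acids whose F-hat is exactly 0 (all observed
    codons used once) carry no information about within-family concentration
    and are excluded from the class mean. An absent 3-fold class is imputed
    as (F2 + F4)/2 per Wright; any other required class fully undefined makes
    ENC undefined. The reported value is clamped to [20, 61].
    """
    class_fbar: dict = {}
    for k, aas in code.degeneracy_classes.items():
        if k == 1:
            continue
        fvals = []
        for aa in aas:
            if aa in counts:
                f = _family_homozygosity(counts[aa])
                if f is not None and f > 0:
                    fvals.append(f)
        if fvals:
            class_fbar[k] = sum(fvals) / len(fvals)
    required = [k for k in code.degeneracy_classes if k != 1]
    for k in required:
        if k not in class_fbar:
            if k == 3 and 2 in class_fbar and 4 in class_fbar:
                class_fbar[3] = (class_fbar[2] + class_fbar[4]) / 2.0
            else:
                raise UndefinedMetricError(
                    f"ENC undefined: no usable family of size {k}"
                )
    n_singletons = len(code.degeneracy_classes.get(1, ()))
    value = float(n_singletons)
    for k in required:
        m_k = len(code.degeneracy_classes[k])
        value += m_k / class_fbar[k]
    if clamp:
        return min(max(value, ENC_MIN), ENC_MAX)
    return value


def enc_from_sequence(seq: str, code: GeneticCode, clamp: bool = True) -> float:
    return enc(codon_counts(seq, code), code, clamp=clamp)


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous positions of an in-frame sequence."""
    s = seq.upper().replace("U", "T")
    usable = [n for n in s if n in NUCLEOTIDES]
    if not usable:
        raise UndefinedMetricError("no unambiguous nucleotides")
    return sum(1 for n in usable if n in "GC") / len(usable)


def gc3(seq: str) -> float:
    """G+C fraction at third codon positions (unambiguous codons only)."""
    thirds = [c[2] for c in usable_codons(seq)]
    if not thirds:
        raise UndefinedMetricError("no unambiguous codons")
    return sum(1 for n in thirds if n in "GC") / len(thirds)


def expected_enc(gc3_value: float) -> float:
    """Wright's null-curve ENC expected from GC3 alone:
    EENC(s) = 2 + s + 29 / (s^2 + (1-s)^2)."""
    s = float(gc3_value)
    if not 0.0 <= s <= 1.0:
        raise ValidationError(f"GC3 must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def denc(eenc: float | None, oenc: float | None) -> float | None:
    """DENC = EENC - OENC; positive when bias exceeds the composition null."""
    if eenc is None or oenc is None:
        return None
    return eenc - oenc


def _fully_degenerate_boxes(code: GeneticCode) -> set:
    """First-two-nucleotide prefixes whose 4 completions encode one amino acid
    belonging to a 4- or 6-fold family."""
    boxes = set()
    for n1 in NUCLEOTIDES:
        for n2 in NUCLEOTIDES:
            aas = {code.codon_to_aa[n1 + n2 + n3] for n3 in NUCLEOTIDES}
            if len(aas) == 1:
                aa = aas.pop()
                if aa != "*" and len(code.aa_to_codons[aa]) in (4, 6):
                    boxes.add(n1 + n2)
    return boxes


def degenerate_gc_usage(seq: str, code: GeneticCode) -> float:
    """G+C fraction at fully degenerate third positions (4-/6-fold families).

    For 6-fold families only the 4-fold codon box counts (e.g. CTN for Leu,
    not TTA/TTG), since only there is the third position fully degenerate.
    """
    boxes = _fully_degenerate_boxes(code)
    thirds = [c[2] for c in usable_codons(seq) if c[:2] in boxes]
    if not thirds:
        raise UndefinedMetricError("no codons in fully degenerate 4-/6-fold boxes")
    return sum(1 for n in thirds if n in "GC") / len(thirds)


def profile_sequence(seq: str, code: GeneticCode, taxon: str,
                     gene_id: str = "genome-wide") -> CodonBiasProfile:
    """Full codon-bias profile of one sequence; undefined metrics become None."""

    def attempt(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    counts = attempt(codon_counts, seq, code)
    n_used = sum(c for aa in counts.values() for c in aa.values()) if counts else 0
    oenc_raw = attempt(enc, counts, code, False) if counts else None
    oenc = min(max(oenc_raw, ENC_MIN), ENC_MAX) if oenc_raw is not None else None
    gc_val = attempt(gc_content, seq)
    gc3_val = attempt(gc3, seq)
    eenc_val = expected_enc(gc3_val) if gc3_val is not None else None
    return CodonBiasProfile(
        taxon=taxon,
        gene_id=gene_id,
        oenc=oenc,
        oenc_raw=oenc_raw,
        gc=gc_val,
        gc3=gc3_val,
        eenc=eenc_val,
        denc=denc(eenc_val, oenc),
        gc_degenerate_46=attempt(degenerate_gc_usage, seq, code),
        n_codons_used=n_used,
    )
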