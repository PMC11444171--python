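"""Gene-by-gene paired comparisons of selection metrics across trait categories.

The unit of replication is the gene: for each gene the branch-category codon
model yields one omega, dN and dS per category, and category pairs are
compared with a paired Wilcoxon signed-rank test over genes, alongside the
fraction of genes following the expected direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MIN_PAIRS = 6
METRICS = ("omega", "dN", "dS")


@dataclass
class WilcoxonResult:
    statistic: float  # W = min(W+, W-) after dropping zero differences
    p_value: float
    n_used: int  # non-zero differences
    method: str  # "exact" | "normal" | "degenerate"


@dataclass
class DirectionResult:
    proportion_following: float  # strict, over all n pairs
    proportion_opposing: float
    n_ties: int
    n: int


def paired_wilcoxon(a, b) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's rule), ties are mid-ranked.
    The exact null distribution (computed by convolution over the signed
    mid-ranks) is used for n <= 25; beyond that the normal approximation
    with continuity and tie correction. Pairs with a missing value are
    removed before testing; fewer than 6 complete pairs is refused.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    d = a[ok] - b[ok]
    if d.size < MIN_PAIRS:
        raise ValueError(
            f"need >= {MIN_PAIRS} complete pairs for the signed-rank test, got {d.size}"
        )
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; test degenerate, p = 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    n = d.size
    if n <= 25:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        p = _normal_two_sided_p(ranks, d, w)
        method = "normal"
    return WilcoxonResult(statistic=w, p_value=min(p, 1.0), n_used=n, method=method)


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """P(min(W+, W-) <= w) under the symmetric null, by convolution.

    Mid-ranks can be half-integers, so everything is doubled to integers.
    The null distribution of 2*W+ is symmetric about its total, so the
    two-sided p is twice the lower tail at 2*w.
    """
    d2 = np.rint(2.0 * ranks).astype(int)
    total = int(d2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in d2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2.0 * w))
    lower = float(dist[: w2 + 1].sum())
    return min(1.0, 2.0 * lower)


def _normal_two_sided_p(ranks: np.ndarray, d: np.ndarray, w: float) -> float:
    """Normal approximation with continuity correction and tie correction."""
    n = d.size
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    # w is the lower of the two sums, so apply the correction toward the mean
    z = (w - mu + 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.cdf(z)))


def proportion_following(a, b, expected_direction: str = "a_less") -> DirectionResult:
    """Fraction of genes strictly following the expected direction.

    Ties count toward neither direction; following + opposing + tie
    fractions sum to 1 over the n complete pairs.
    """
    if expected_direction not in ("a_less", "a_greater"):
        raise ValueError("expected_direction must be 'a_less' or 'a_greater'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        return DirectionResult(0.0, 0.0, 0, 0)
    less = int((a < b).sum())
    greater = int((a > b).sum())
    ties = n - less - greater
    follow = less if expected_direction == "a_less" else greater
    oppose = greater if expected_direction == "a_less" else less
    return DirectionResult(follow / n, oppose / n, ties, n)


def significance_stars(p: float) -> str:
    """Figure-caption star convention: * p<=0.05, ** p<=0.001, *** p<=0.0001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if p <= 1e-4:
        return "***"
    if p <= 1e-3:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Gene x category tables and pairwise summaries
# ---------------------------------------------------------------------------

def build_gene_category_table(estimates) -> pd.DataFrame:
    """Wide table from per-gene CategoryEstimates: rows = genes, columns =
    MultiIndex (metric, category). Genes with a non-converged fit contribute
    NaN for every metric (they are excluded from comparisons)."""
    records = []
    for est in estimates:
        for cat in est.categories:
            ok = est.converged
            records.append({
                "gene_id": est.gene_id,
                "category": cat,
                "omega": est.omega[cat] if ok else np.nan,
                "dN": est.dN[cat] if ok else np.nan,
                "dS": est.dS[cat] if ok else np.nan,
            })
    long = pd.DataFrame.from_records(records)
    if long.empty:
        raise ValueError("no estimates to tabulate")
    wide = long.pivot(index="gene_id", columns="category", values=list(METRICS))
    return wide.sort_index()


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(metric, category) medians plus long-format export columns."""
    med = table.median(axis=0, skipna=True)
    out = med.rename("median").reset_index()
    out.columns = ["metric", "category", "median"]
    out["n_genes"] = [
        int(table[(m, c)].notna().sum()) for m, c in zip(out["metric"], out["category"])
    ]
    return out


def to_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Violin-plot-ready long table: gene_id, metric, category, value."""
    long = table.stack(level=1, future_stack=True).reset_index()
    return long.melt(id_vars=["gene_id", "category"], var_name="metric",
                     value_name="value").dropna(subset=["value"])


def compare_categories(table: pd.DataFrame, pairs, metrics=METRICS,
                       expected_direction: str = "a_less") -> pd.DataFrame:
    """Paired tests for each (metric, category pair) over genes.

    Emits raw two-sided p, caption stars, a Holm-corrected column (per
    metric family), direction proportions and per-category medians.
    """
    rows = []
    for metric in metrics:
        for cat_a, cat_b in pairs:
            va = table[(metric, cat_a)].to_numpy(dtype=float)
            vb = table[(metric, cat_b)].to_numpy(dtype=float)
            ok = ~(np.isnan(va) | np.isnan(vb))
            row = {
                "metric": metric, "category_a": cat_a, "category_b": cat_b,
                "n": int(ok.sum()),
                "median_a": float(np.nanmedian(va)) if ok.any() else np.nan,
                "median_b": float(np.nanmedian(vb)) if ok.any() else np.nan,
            }
            try:
                res = paired_wilcoxon(va, vb)
                row.update(W=res.statistic, p=res.p_value, method=res.method)
            except ValueError:
                row.update(W=np.nan, p=np.nan, method="skipped")
            direction = proportion_following(va, vb, expected_direction)
            row.update(
                proportion_following=direction.proportion_following,
                n_ties=direction.n_ties,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "na" for p in out["p"]]
    out["p_holm"] = np.nan
    for metric in out["metric"].unique():
        mask = (out["metric"] == metric) & np.isfinite(out["p"])
        if mask.any():
            out.loc[mask, "p_holm"] = _holm(out.loc[mask, "p"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
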