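# Methods

`phylosel` measures how the intensity of purifying selection on protein-coding
genes varies with organismal traits mapped onto a phylogeny. It combines four
pieces: a branch-category codon substitution model, discrete-trait ancestral
reconstruction to label branches by trait category, codon-usage-bias
profiling, and gene-by-gene paired comparisons across categories. A
synthetic-study generator with known ground truth closes the loop so every
stage can be validated end to end.

## Branch-category codon model

The substitution process over the sense codons follows the Goldman–Yang
parameterization: instantaneous rates are nonzero only between codons
differing at a single nucleotide position, and

q_ij = pi_j · kappa^[transition] · omega^[nonsynonymous],

with `pi` the stationary codon frequencies, `kappa > 0` the
transition/transversion rate ratio and `omega = dN/dS` the
nonsynonymous/synonymous rate ratio. Each category's generator is rescaled so
the expected substitution rate at stationarity is one; branch lengths are
therefore in expected substitutions per codon. In the variable-ratio branch
model every branch of the phylogeny carries a category label (for example the
four body architectures U, M, Sp, Sc) and all branches of a category share
one omega, while kappa, pi and the per-branch lengths are shared nuisance
parameters. Branch lengths are free per branch; the category structure
applies to omega only.

Codon frequencies default to F3x4 (position-specific nucleotide frequencies
multiplied per codon, stops excluded, renormalized); F1x4 and empirical codon
frequencies are available. Zero-frequency nucleotides are floored at 1e-6
before renormalization so no codon has probability zero.

The likelihood is computed by Felsenstein pruning over aliased site patterns.
Gap codons and codons containing ambiguity characters are treated as missing
data (their partial likelihood is one in every state). The tree is used as
rooted with root prior pi; by reversibility the likelihood is invariant to
root placement, which the tests verify. Transition matrices come from the
eigendecomposition of the symmetrized reversible generator
(`D^{1/2} Q D^{-1/2}` with `D = diag(pi)`).

### Numerical choices

* **Per-node rescaling.** Partial likelihood vectors are rescaled by their
  per-pattern maximum, with log scalers accumulated, so deep trees do not
  underflow.
* **Eigen round-off.** Transition probabilities several mutational steps away
  can be smaller than the eigendecomposition's absolute error (~1e-14) and
  come out marginally negative; pruning messages are clamped at zero.
  Patterns whose conditional likelihood falls below 1e-290 are held at that
  floor (a large, finite penalty) and contribute zero gradient, so the
  optimizer backs away from such regions instead of aborting.
* **Analytic gradients.** Derivatives with respect to every branch length are
  obtained from one additional pre-order ("outside") pass; derivatives with
  respect to kappa and each omega use the eigenbasis divided-difference
  (Fréchet) formula. A finite-difference cross-check is part of the test
  suite.
* **Optimization.** L-BFGS-B on the log scale of all parameters, with bounds
  omega ∈ [1e-4, 20], kappa ∈ [0.1, 50], t ∈ [1e-8, 30]. The first start
  takes branch lengths from the input tree with kappa = 2, omega = 0.2; the
  default two restarts jitter rate parameters (lognormal sd 0.3) and lengths
  (sd 0.1). A restart stranded more than 100 log-likelihood units above the
  best is discarded and redrawn (it signals a line-search failure in a
  floored region, not a genuine local optimum). Convergence requires a
  projected-gradient infinity norm below 1e-4 on the log scale and, with two
  or more starts, agreement of the best two log-likelihoods within 1e-4.
  Two starts (rather than three) are the default because converged restarts
  agree to ~1e-11 in practice, so a third start buys almost nothing for a
  50% cost increase; `FitConfig.n_starts` raises it.
* **Unrooted parameterization.** Under a reversible model a binary root's
  two edges are not separately identifiable (only near-identifiable when
  their categories differ — a spurious extra degree of freedom that would
  distort nested-model comparisons). The likelihood engine therefore
  collapses a binary root to a trifurcation, summing the two edge lengths;
  the merged branch takes the category of the longer merged segment. This is
  the same convention an unrooted branch-labeled tree forces in standard
  codon-model software, and it makes the single-ratio and variable-ratio
  models differ by exactly the number of extra omegas.

### dN/dS decomposition

Site counts use the mutational-opportunity definition: S/(S+N) is the
synonymous fraction of the stationary substitution flux of the neutral
(omega = 1) process, and S + N = 3 per codon. For a branch of length t in
category c with synonymous flux fraction fS(omega_c),

dS_b = t · fS / (S/3),  dN_b = t · (1 − fS) / (N/3),

so at omega = 1 both equal t. A category's dN (dS) is the **sum** over its
branches — the total divergence attributable to the category. The paper-style
per-gene tables report one omega, dN and dS per category; per-branch values
are retained in `CategoryEstimates.branch_records` so alternative
aggregations (mean, length-weighted) can be recomputed without refitting.

## Trait mapping

Discrete traits evolve under a continuous-time Markov (Mk) model. The default
is equal rates (the smallest adequate model for two-state traits);
all-rates-different is available. Rates are fit by bounded quasi-Newton on
the log scale; the root prior is the stationary distribution of the fitted
rate matrix. Marginal ancestral probabilities come from combined post-order
("down") and pre-order ("out") passes, equivalent to re-rooting at every
node.

Stochastic maps are drawn by sampling node states from their joint posterior
(downward sampling from the root) and then sampling each branch's path
conditional on its endpoint states by uniformization (virtual jumps; the jump
count is drawn from its exact conditional distribution, the jump chain by
bridge sampling, jump times as uniform order statistics). The per-branch
summary records both the mean fraction of branch time spent in each state and
the fraction of maps in which each state occupies the branch majority, plus
Monte-Carlo standard errors. The default 1000 maps are collapsed to a single
labeling by majority time fraction; ties break toward the parent branch's
label, then alphabetically. A threshold rule (`tau`) flags low-occupancy
branches as ambiguous and refuses to proceed unless forced. Labels may also
be supplied directly as a marked Newick file, bypassing estimation — the
route used when branch categories come from a prior study.

Combined-trait labelings (e.g. body architecture × life cycle) are built by
pairing two labelings of the same topology through an explicit allowed-pair
alphabet; any branch whose pair falls outside the alphabet is reported by
name rather than silently coerced.

## Codon-usage bias

The observed effective number of codons (OENC) is Wright's estimator: per
amino acid with usage n ≥ 2, F̂ = (nΣp̂² − 1)/(n − 1); per family-size class
the mean F̄ is taken over amino acids with informative F̂ (F̂ = 0, meaning
every observed codon used once, carries no concentration signal and is
excluded); ENC = m₁ + Σ m_k/F̄_k with class sizes m_k recomputed from the
genetic code in use. A missing 3-fold class is imputed as (F̄₂ + F̄₄)/2; any
other class with no information makes ENC undefined (reported missing, with
the reason). Reported values are clamped to [20, 61]; the raw estimator value
is stored alongside. Because F̂ is unbiased but ENC is a convex function of
it, the raw estimator drifts by O(1/n); the tests check scale behavior at
realistic depth rather than asserting exact invariance on toy counts.

The composition-only expectation is Wright's null curve
EENC(s) = 2 + s + 29/(s² + (1−s)²) with s = GC3, and DENC = EENC − OENC:
zero when composition alone explains the bias, positive when codon usage is
more constrained than composition predicts. GC usage at degenerate positions
is restricted to third positions of fully degenerate codon boxes of 4- and
6-fold families (for 6-fold families only the 4-fold box qualifies; the
2-fold satellites are excluded), with boxes derived from the genetic code.

Taxa using the dasycladacean nuclear code are profiled under NCBI translation
table 6, where TAA/TAG encode glutamine; its family structure (Gln becomes
4-fold, 63 sense codons) is recomputed, not patched. Per-species profiles
default to concatenated-gene computation; a per-gene mode is provided since
either convention is defensible.

## Comparative statistics

The unit of replication is the gene: each converged fit contributes one
omega, dN and dS per category, and category pairs are compared with a
two-sided paired Wilcoxon signed-rank test over genes. Zero differences are
dropped (Wilcoxon's rule), ties are mid-ranked; for n ≤ 25 the exact null
distribution is built by convolution over the signed mid-ranks (doubled to
integers), beyond that the normal approximation with continuity and tie
corrections applies. Fewer than six complete pairs is refused as powerless.
Raw p-values are reported with the star convention * p ≤ 0.05, ** p ≤ 0.001,
*** p ≤ 0.0001; a Holm-corrected column is emitted alongside for users who
want family-wise control, but the primary report is uncorrected. The
direction summary counts genes strictly following the expected ordering;
ties count toward neither side, and following + opposing + tied fractions
sum to one. Genes with any non-converged category fit are excluded from all
comparisons for every metric, with counts in the run manifest.

## Synthetic studies

The generator emulates the shape of a multi-gene comparative study: one
ultrametric birth–death species tree (forward Gillespie simulation stopped
when the tip count is reached, extinct lineages pruned, rescaled to a target
height), a coupled trait history, and many single-copy gene alignments
evolved under the branch-category codon process with the true labels.

The default desk-scale scenario is 16 taxa × 20 genes × 300 codons with the
four body-architecture categories at true omega {U: 0.05, M: 0.15, Sp: 0.3,
Sc: 0.3} and kappa = 2 — strong purifying selection on unicellular branches,
progressively relaxed on structurally complex ones, at roughly the omega
magnitudes typical of conserved single-copy genes. Tree height is 1.0
expected substitutions per codon root-to-tip (deep-divergence territory),
birth 1.0 / death 0.3, and per-gene lognormal rate multipliers (sd 0.3)
create the gene-level variation the paired tests consume. The trait history
runs on a coupled pair-state space (UH, MH, MHD, SpH, ScH) in which the
haploid–diploid life cycle can only arise on multicellular branches,
reproducing the empirical confounding between the two traits; body moves at
rate 0.5, life-cycle switching at 0.8. A scenario is resampled (up to 100
attempts, attempts recorded) until every model's categories sit on at least
`min_branches_per_category` branches — 2 by default, so no category's omega
rests on a single branch; small test scenarios relax this to 1. A fraction
(default 25%) of taxa have their life-cycle state masked in the emitted trait
table, mimicking missing published information; the truth is retained in the
ground-truth JSON. All randomness derives from one master seed through named
substreams, and regeneration is byte-identical.

What the generator does **not** emulate: indels and alignment error, rate
variation among sites, lineage-specific codon frequencies, and selection on
synonymous sites. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to the
violations real data bring.

## Problem sizes used in the test suite

The suite refits simulated data at sizes chosen to exercise each claim while
staying desk-scale: parameter recovery at 50 taxa × 500 codons (single
fit); likelihood-ratio null calibration over 50 replicates of 8 taxa × 300
codons — large enough that the chi-square reference for the statistic is
well calibrated (at, say, 6 taxa × 150 codons the many branch-length
nuisances leave the statistic visibly heavier than chi-square(1), a
small-sample effect, not an error) — with the variable-ratio fit
warm-started from the single-ratio solution so the statistic is
non-negative by construction; and the end-to-end recovery run on the
default 16 × 20 × 300 fixture. The rank-order recovery
check is evaluated over genes whose fits converged, matching the package's
own rule that non-converged genes enter no comparison.

## Known limitations

* Site-homogeneous model only: no among-site rate variation or site/branch-
  site selection classes.
* The per-category dN/dS sums depend on the category's total branch length;
  comparisons across categories with very different representation lean on
  the paired (within-gene) design to stay meaningful.
* Wright's null curve is an approximation; |DENC| < 2 is the documented
  tolerance under the pure-composition null.
* The Mk machinery targets small state spaces (2–5 states); it uses dense
  matrix exponentials and is not tuned for large alphabets.
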