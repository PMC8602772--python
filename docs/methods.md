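# Methods

## Problem and model

Reference-based cell type annotation assigns a type label to each cell of
an unlabeled scRNA-seq query using an annotated reference. This package
repurposes two bulk-deconvolution estimators for that task. The reference
is collapsed into a pseudo-bulk signature matrix **H** whose column
*b<sub>c</sub>* is the mean log-normalized profile of type *c*; a query
cell's profile **y** is modeled as

y = Σ<sub>c</sub> w<sub>c</sub> b<sub>c</sub> + ε.

Because a single cell contains exactly one type rather than a mixture, the
estimated weight vector **w** is read as a score over types and the cell
is assigned argmax<sub>c</sub> w<sub>c</sub>.

* **CP (constrained projection)** estimates **w** by quadratic
  programming: minimize ‖y − Hw‖² subject to w ≥ 0 and Σw = 1. The
  sum-to-one equality follows the mixture interpretation; a Σw ≤ 1
  variant is available (`sum_constraint="le"`) for compatibility with
  implementations that use the inequality form.
* **RPC (robust partial correlations)** estimates **w** by robust
  multivariate linear regression of y on H with a Huber loss, fitted by
  iteratively reweighted least squares. Coefficients are unconstrained
  and may be negative; the intercept absorbs global platform shifts and
  is excluded from the argmax.

## Preprocessing

Cells detecting fewer than 200 genes and genes expressed in fewer than 3
cells are removed (cell filter first). Counts are log-normalized:
entry (g, j) ↦ ln(1 + 10⁴ · x<sub>gj</sub> / colsum<sub>j</sub>); an
all-zero cell stays all-zero. The pseudo-bulk is the per-type arithmetic
mean of normalized profiles, columns in sorted label order.

The signature is restricted to 2000 highly variable genes. Genes are
scored by the residual of log₁₀ variance above a lowess trend in log₁₀
mean (frac 0.3, two robustifying iterations), i.e. variance beyond what
expression level alone predicts; ties break on gene identifier. The
ranking is computed **on the pseudo-bulk itself**, so "variance" is
variation across the C type profiles: this concentrates the signature on
type-discriminating genes and keeps its condition number small (the
condition number is logged, not optimized). Scoring on the single-cell
reference instead is possible through the same function but is markedly
worse when types are similar, because weak between-type variance is
drowned by technical noise. Known limitation of the trend residual: a
gene whose mean is isolated on the mean axis acts as a leverage point and
its own variance is absorbed into the trend, so a lone extreme-mean gene
can be under-ranked; with genome-scale gene sets the mean axis is densely
populated and this does not arise.

Marker detection (used for export, not by CP/RPC) is a one-vs-rest
two-sided Wilcoxon rank-sum test restricted to genes expressed in ≥ 25%
of cells of either group with natural-log fold change of back-transformed
means > 0.25 (positive only by default); the exact null distribution is
used when both groups have ≤ 10 tie-free observations, the
tie-corrected normal approximation otherwise. Top 10 genes per type,
ranked by p then |logFC| then gene id.

Feature downsampling preserves the original log-count profile: genes are
binned into 20 equal-width bins of ln(1 + total count), the kept budget
is allocated to bins by largest remainder, and sampling is uniform
without replacement within bins.

## Estimator numerics

* CP reduces each cell's problem to the C-dimensional QP with
  Q = HᵀH, c = Hᵀy (computed once per dataset), solved by SLSQP with
  ftol 10⁻¹⁴ and up to 500 iterations from the uniform start; solutions
  satisfy the simplex constraints to 10⁻⁸ and are checked in the test
  suite against a 0.01-step simplex-grid search. Cells are fitted
  independently — no warm starts — so results are order-independent.
* RPC's IRLS uses the Huber weight with tuning constant 1.345 (95%
  efficiency under Gaussian errors) on residuals scaled by MAD/0.6745,
  starting from ordinary least squares, stopping when the maximum
  relative coefficient change falls below 10⁻⁶ or after 100 iterations
  (with a warning on non-convergence). When the residual scale is
  numerically zero — an (almost) exact fit — the OLS solution is
  returned directly, which is also the Huber optimum. When no
  standardized residual exceeds 1.345 the estimate coincides with OLS;
  the suite verifies this and the robustness advantage under 5%
  contamination against a closed-form OLS oracle.
* Argmax ties (exact equality of weights) resolve to the alphabetically
  first type name, for determinism. Optional rejection labels a cell
  "unknown" when its largest weight is below a threshold; it is off by
  default and exists to plug CP/RPC into the leave-out harness.

## Synthetic data

`simulate_paired` draws grouped counts from a gamma-Poisson hierarchy:
gene base means ~ Gamma(shape 0.6, rate 0.3); a fraction `de_prob` = 0.1
of genes per group receives a multiplicative log-normal DE factor
(location 0.1, scale `de_fac_scale`, inverted with probability 0.5);
profiles are renormalized and scaled by log-normal library sizes
(location 11, scale 0.2); a trended over-dispersion
(BCV 0.1, 60 df inverse-chi-square) inflates each mean through a Gamma
draw before Poisson sampling. The *raw* assay zeroes each entry of the
*true* assay independently with probability
logistic(shape · (ln μ − mid)), default shape −0.5 and midpoint 1, so
dropout falls with expression. Group sizes follow the requested
proportions by largest-remainder rounding. Structural draws (which genes
are DE and their factor magnitudes before scaling) come from a separate
`structure_seed`, so a sweep over DE scales shares its DE gene set and
differs only in effect magnitude.

Named designs: `base` (4000 genes × 2000 cells, proportions
10/30/30/10/20%), `de_sweep` (10,000 × 2000, 5 equal groups, scale
vectors low (0.1, 0.3, 0.1, 0.3, 0.2) through high (0.7, 0.9, 0.7, 0.9,
0.8)), `class_sweep` (20,000 × 10,000, N = 10…50 equal groups), `rare`
(10,000 × 2000, 9 groups from 51.25% down to 0.15%), and `scale_sweep`
(20,000 genes, 5000–50,000 cells).

The generator emulates group structure, depth variation, over-dispersion
and expression-dependent dropout. It does **not** emulate batch effects,
outlier genes, doublets, ambient RNA, trajectories, or gene–gene
correlation beyond the shared library size — so passing benchmarks here
show method behaviour under clean gamma-Poisson assumptions, not
performance on real tissue atlases.

## Evaluation

Overall accuracy is exact label agreement. ARI is the Hubert–Arabie
chance-adjusted pair-counting index from the contingency table.
V-measure is the harmonic mean of homogeneity (1 − H(T|P)/H(T)) and
completeness (1 − H(P|T)/H(P)) with natural-log entropies and the
conventions h = 1 when H(T) = 0, v = 0 when h + c = 0. Per-type accuracy
is recall per true type. "unknown" predictions count as wrong for
accuracy and as their own cluster for ARI/V-measure, except in the
leave-out scheme, where metrics are computed over cells whose true type
remains in the reference and the fraction of held-out cells labeled
"unknown" is reported separately.

Schemes: stratified 5-fold cross-validation (round-robin within type, so
rare types reach both sides of every split); inter-dataset prediction
(true assay → raw assay); the DE-scale, class-number and rare-population
sweeps; leave-out-k (k ∈ {1, 2}; all C-choose-k combinations, e.g. 5 and
10 evaluations for C = 5); and query feature downsampling at 5000 /
10,000 / 15,000 genes with 5 repeats. All schemes are deterministic given
their seeds; reports carry seeds, spec hashes and the package version.

## Problem sizes used by the test suite and acceptance script

The headline checks run at the designs' full sizes: 5 seeds of the base
design (4000 × 2000) for CP, 5 seeds of the low-DE design
(10,000 × 2000) for RPC, and 10 seeds of the rare design (10,000 × 2000)
for both methods. Unit and property tests use small instances (hundreds
of genes, ~100–600 cells) chosen so each oracle comparison runs in
seconds; the class-number and cell-count sweeps default to their smaller
settings (N ≤ 20) and expose the full ranges as options.

## Known limitations

* RPC coefficients are not probabilities; they are reported raw.
* The rejection threshold is an extension without a principled default;
  it operates on CP's simplex weights or RPC's raw coefficients, which
  are on different scales.
* The simulator does not replicate any particular RNG stream of other
  generators; only the distributional model is shared.
* Wilcoxon marker p-values are not multiplicity-adjusted (ranking only).
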