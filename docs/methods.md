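# Methods

## Relative quantification (2^−ΔΔCt)

For gene *g* and sample *s*, ΔCt(g,s) = Ct(g,s) − Ct(hk,s) normalizes out
per-sample input differences via a housekeeping gene; ΔΔCt subtracts a
per-gene calibrator reference (either a calibrator sample's ΔCt or a
supplied per-gene ΔCt vector); the reported value is 2^−ΔΔCt. The
housekeeping row must be complete and is excluded from the output. Missing
Ct values propagate to missing expression. Adding a constant to all Ct
values of a sample leaves the result unchanged (it cancels through the
housekeeping subtraction) — this is a tested invariant. Only single-gene
housekeeping normalization is implemented; multi-gene geometric-mean
normalization is out of scope.

## Classifier input

2^−ΔΔCt values are heavily right-skewed and nonnegative, which penalized
linear least squares handles poorly, so the design matrix defaults to
log2(value + ε), ε = 1e−6 (configurable, `none` available). Genes missing
in more than 20% of the comparison's samples are dropped with a warning;
remaining missing values are imputed with the training-fold gene median.
Per-gene centering and scaling (sample SD) are always computed on the
stated fit samples only — inner-training, outer-training, or all samples,
depending on the stage — and applied to held-out rows, so no test
information reaches the standardization. Zero-variance genes get scale 1
and are flagged. The first class of a comparison maps to −1 and the second
to +1; the mapping is stored in the outputs.

## Univariate screen

Per-gene two-sided Mann–Whitney tests: exact enumeration when
n_a·n_b ≤ 400 and the pooled values are tie-free, otherwise the normal
approximation with tie and continuity corrections (both code paths are
exposed through the results' `method` field). Raw p-values are reported
with significance tiers (0.05 / 0.01 / 0.0001 by default) because that is
how targeted-panel results are conventionally read; a Benjamini–Hochberg
column is emitted alongside for transparency. Top-k ranking breaks p-value
ties by absolute log2 median ratio (descending), then gene symbol — the
ratio uses a 1e−6 pseudocount so zero medians stay ordered.

## The ℓ1+ℓ2 solver

Weights minimize (1/n)‖Y − Xβ‖² + τ‖β‖₁ + λ‖β‖² with no intercept
(labels are ±1 and columns standardized). Optimization is damped iterative
soft-thresholding,

    β⁽ᵏ⁺¹⁾ = S_{τ/(2σ)}( [β⁽ᵏ⁾(σ − λ) + (1/n)Xᵀ(Y − Xβ⁽ᵏ⁾)] / σ ),

with fixed step constant σ = λ + ‖XᵀX‖₂/n, which majorizes the smooth
part's Lipschitz constant and makes the objective provably non-increasing
(asserted on the stored iteration history in tests). Convergence:
‖β⁽ᵏ⁺¹⁾ − β⁽ᵏ⁾‖ ≤ tol·‖β⁽ᵏ⁾‖ with tol = 1e−6, max_iter = 10,000;
non-convergence sets a flag rather than raising. Solutions are checked in
the test suite against a cyclic coordinate-descent oracle run to 1e−12 and
against KKT subgradient conditions (residual < 1e−6); τ = 0 reproduces the
ridge closed form. Warm starts along a decreasing τ grid speed up grid
evaluation; warm-start independence of the solution is tested. β = 0 is
optimal exactly when τ ≥ τ_max = 2‖XᵀY‖_∞/n, which anchors the grid.

After selection, the model used for prediction is by default a ridge refit
on the selected support (off-support weights exactly 0, refit λ equal to
the selected λ): the ℓ1 penalty's shrinkage biases weight magnitudes, and
refitting is the standard second stage for this method family. A `refit =
False` mode keeps the raw penalized weights. An empty support falls back
to the majority training class (logged). Scores of exactly 0 predict +1 by
convention (logged).

## Nested cross-validation and stability selection

Outer loop: k_outer = 5 stratified folds (defaults chosen for class sizes
in the 12–29 range; seeded and fully deterministic). For each outer
training set, an inner k_inner = 4 stratified CV evaluates the full
(τ, λ) grid: 20 geometric τ values from τ_max down to τ_max/1000 (τ_max
computed once on the full comparison, fixing the grid's scale) crossed
with λ ∈ {0.01, 0.1, 1, 10} on the standardized scale.

Model selection minimizes total inner-validation misclassification.
Because validation folds hold only a handful of samples, the 0/1 error is
a coarse integer and large parts of the grid tie at the minimum; among
those ties the validation square loss of the real-valued scores against
the ±1 labels — the quantity the model itself minimizes — decides, and
only residual ties fall back to the sparsity preference (larger τ, then
smaller λ). Without the square-loss step the selection collapses onto
near-minimal supports and measurably under-recovers planted genes on the
synthetic benchmark; with it the choice tracks predictive fit while
remaining sparsity-seeking.

Each outer fold contributes the non-zero-weight genes of the model fit on
its training set at (τ*, λ*), plus predictions on its held-out test fold.
A gene's frequency score is the percentage of outer folds selecting it;
genes at ≥50% form the signature (the threshold is fixed; a
threshold-vs-count scan table is emitted so the slope change can be
inspected by eye, and no automatic threshold rule is invented). Reported
accuracy and MCC are pooled over the outer-fold held-out predictions
(per-fold values are also emitted); pooling was chosen over fold-averaging
because with 8-sample test folds per-fold metrics are extremely grainy.

MCC on a degenerate confusion table (an empty margin) is defined as 0 and
flagged. The two-tailed Student-t critical-value helper supports the
conventional check that two subgroups may be pooled before a comparison.

## Enrichment

Upper-tail hypergeometric test per gene set: p = P(X ≥ k) for X ~
Hypergeom(N, K, n) with N the universe size, K the set's universe members,
n the mapped signature size and k the overlap. Over-representation only;
enrichment ratio (k/n)/(K/N) > 1 marks the enriched direction. Sets with
overlap < 3 are excluded by default (the threshold can alternatively be
applied to set size). The universe defaults to the union of set members;
for targeted panels the panel's gene list is the statistically honest
universe, and a genome-scale universe file can be supplied instead — the
choice changes every p-value and is therefore logged. BH-adjusted p-values
are emitted alongside the raw ones.

## Synthetic data generator

The generator emulates a two-class targeted qPCR study, not genome-wide
expression. Per-gene log2 abundance is multivariate normal: gene baseline
means ~ N(0, 2²) (panel genes span a wide dynamic range around the
calibrator), within-class biological SD 1.0 log2 unit, and equicorrelated
blocks — default (8, 0.6), (8, 0.6), (8, 0.4) — mimicking co-regulated
pathway modules (positive-definite by construction for ρ ∈ [0, 1)).
Planted genes (default 10 of 91) receive a ±2.0 log2-unit class shift with
random recorded sign — a 4-fold change, the magnitude qPCR panels are
designed to detect. Technical noise is Gaussian on the Ct scale (default
SD 0.25 cycles ≈ 19% multiplicative noise), the structure qPCR error
actually has. Class sizes default to 12 vs 29, the extreme pairing of the
emulated study design, to stress stratified fold construction; the four
study-shaped benchmarks set (12, 15), (12, 13), (15, 29), (13, 29) with
planted counts 6, 52, 62, 49.

Data are exported through a simulated Ct pipeline (gene-specific baseline
Ct drawn in 24–32 cycles, constant housekeeping gene at Ct 20, per-gene
calibrator ΔCt reference) and converted by the package's own ΔΔCt code, so
synthetic data enter the pipeline exactly as instrument exports would; at
zero technical noise this round-trip is exact (tested). The generator does
not model donor chimerism, cell-subset heterogeneity, batch effects,
missing wells, or probe saturation — passing tests demonstrate that the
pipeline recovers truth under its stated noise model, not that it is
robust to those real-world artifacts.

## Problem sizes used in the checks

The self-contained checks run at desk scale, chosen as the smallest sizes
at which each property is meaningful: solver optimality on 50 random 10×5
problems; metric identities exhaustively on all confusion tables with ≤12
samples; enrichment tails on (N ≤ 100, K ≤ 20, n ≤ 10) grids plus a
100,000-draw Monte-Carlo cross-check; Mann–Whitney against full
permutation enumeration up to group sizes (4, 4); parameter recovery over
10 seeded benchmark datasets at the default generator conditions; null
calibration over 12 no-effect runs with a reduced grid (10 τ values,
λ ∈ {0.1, 1}, k_inner = 3).

## Known limitations

- The square loss drives both fitting and the tie-breaking model
  selection; logistic or hinge losses are out of scope.
- Signature size is sensitive to the λ grid: larger λ values admit more
  correlated genes. The defaults favor compact signatures.
- With ~8 samples per outer test fold, pooled accuracy/MCC still have
  substantial variance between seeds; multi-seed averages are reported in
  the benchmarks for that reason.
- The frequency threshold is a convention (50%), not an inferred quantity.
- Only two-class comparisons; one housekeeping gene; no paired designs.
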