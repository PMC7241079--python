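# Methods

## Model and objective

The core estimator is a phenotype-supervised sparse multiple canonical
correlation. Two column-standardized blocks X₁ (proteins), X₂ (metabolites)
and a standardized phenotype y are coupled through the bilinear objective

    J(w₁, w₂) = w₁ᵀ Σ₁₂ w₂ + s·(w₁ᵀ σ₁y + w₂ᵀ σ₂y)

with Σ₁₂ and σ_ky sample Pearson correlation matrices. The phenotype is
treated as a fixed third block with scalar weight +1: a scalar block needs
no sparsity, and this reduces the three-block problem to the two optimized
weight vectors that the analysis reports. A single scaling constant s
multiplies both omics–phenotype terms. Constraints per block are
‖w‖₂ ≤ 1 and ‖w‖₁ ≤ c with c = l·√p, l ∈ (0, 1]; l = 1 is effectively
unpenalized and the printed grid values are comparable across block sizes.
When l·√p < 1 the budget is clamped to c = 1 (one active feature), the same
convention as penalized-matrix-decomposition software, since no unit-L2
vector has L1 norm below 1.

### The projection operator

Each block update maximizes a linear function over {‖w‖₂ ≤ 1, ‖w‖₁ ≤ c},
whose solution is soft-threshold-then-renormalize, S(v, δ)/‖S(v, δ)‖₂, with
δ the smallest threshold making the result L1-feasible. Rather than
bisecting on δ — which loses all precision when entries of |v| are tied to
within ~1e−9, because the feasibility map becomes effectively discontinuous
at float resolution — the implementation collapses magnitudes within a
relative 1e−6 band into tie groups and solves the group-mass problem
exactly: maximize Σ t_g M_g subject to Σ M_g ≤ c and Σ M_g²/n_g ≤ 1. On the
collapsed values the per-support feasibility equation is a well-conditioned
quadratic; exactly tied components receive equal within-group mass, which is
optimal there (the objective depends on group masses only, and equal spread
minimizes the L2 cost of a given mass). For generic inputs (no ties) this
reproduces the classic soft-threshold solution exactly. When the budget fits
inside the top tie group (c² ≤ n₁) all mass goes there, the L2 constraint
being slack. The block ascent asserts a non-decreasing objective each
iteration with 1e−4 relative slack covering the tie-collapse approximation.

### Initialization and determinism

w₂ starts at the unit-normalized column sums of |Σ₁₂| — deterministic, no
random restarts. All tie-breaks (one-hot corner, argmax selections, hub
ordering) resolve to the lowest index or lexicographic id. Every stochastic
stage (folds, subsampling, the generator) draws from a named substream of a
single run seed.

## Penalty selection

All 36 pairs from the 6-value grid are evaluated by 5-fold CV. The per-fold
error is the **relative** generalization gap |J_train − J_test| / |J_train|,
with both objectives evaluated using the trained weights on independently
standardized splits. The absolute gap was tried first and is structurally
wrong: J grows with the L1 budget, so an absolute gap always ranks the
sparsest pair best regardless of fit quality. Even the relative surface is
shallow (a few percent spread across the grid), so the pipeline averages the
error over 10 independent fold splits (`cv_repeats`); a single split's
argmin is fold-assignment noise and was observed to jump between opposite
grid corners on identical data. Ties break to smaller l₁+l₂, then smaller
l₁.

## Consensus similarity and module extraction

Each of 100 replicates (default) draws ⌈0.7·p_k⌉ features per block without
replacement, fits the sparse CCA on the subsampled columns, embeds the
weights into full-length vectors and accumulates |w̃w̃ᵀ|. The average is
normalized so the largest off-diagonal entry is 1, the diagonal zeroed, and
edge signs attached from full-data Pearson correlation signs. The
subsampling fraction and replicate count are exposed configuration, chosen
for desk-scale runtime; similarity matrices from independent 200-replicate
runs on planted-signal data agree to better than 10% relative Frobenius
distance.

Modules are average-linkage clusters of D = 1 − similarity cut at 0.999:
with a max-normalized similarity, a cut just below 1 separates any connected
structure from the zero-similarity bulk. Clusters of size ≥ 2 are candidate
modules; everything else forms the complement set used as a negative
control. Trimming keeps within-module edges with weight ≥ τ and drops
isolated nodes.

## Network summary and hyperparameter selection

A network is summarized by the first principal component of its
subjects × nodes submatrix (sign fixed so the largest-|loading| feature
loads positively — the reported ρ sign is therefore a convention), and
scored by Pearson correlation with the phenotype; two-sided p-values use the
t transform t = r√(n−2)/√(1−r²). The sweep records one diagnostics row per
(s, τ): ρ, node and edge counts, protein:metabolite ratio and edge-weight
summary.

Selection among rows passing the acceptance rules (|ρ| ≥ 0.20, both kinds
present, ratio within [0.25, 4]) does **not** take the literal argmax of
|ρ|: differences of ~0.001–0.002 between candidate networks are an order of
magnitude below the sampling error of a correlation at these cohort sizes
(SE ≈ 0.03 at n = 500) and cannot be meaningfully ranked. Rows within 0.01
of the maximum count as tied, and among them the rule prefers the longest
plateau of constant node count across adjacent τ values — the
stability-under-adjacent-hyperparameters heuristic used in manual
diagnostics — then larger τ (sparser, stronger-edged), then smaller s. On
planted-signal data this reliably selects the plateau where the network is
exactly the planted module.

## Preprocessing

The metabolite chain is fixed: (1) run-day normalization — each observed
value divided by its feature's run-day median and multiplied by the
feature's overall median, medians over observed values only; (2) outlier
subjects — features z-scored across subjects (zero-variance features
contribute z = 0), each subject's aggregate is the median of its feature
z-scores, and subjects beyond 3.5 SDs of the cohort's aggregate distribution
are removed (the aggregate is median-of-z rather than z-of-median; the
wording is ambiguous and this reading is the one tested); (3) features
missing in strictly more than 20% of subjects are dropped; (4) KNN
imputation across *features* (k = 10): neighbors ranked by Euclidean
distance on co-observed subjects, on the raw pre-log scale, matching the
stated processing order; a missing cell takes the unweighted mean of its k
nearest observed candidates (all of them if fewer qualify, the feature mean
if none); (5) natural log, then per-feature centering and scaling (ddof 1).
Proteomic inputs are assumed vendor-normalized and only receive step (5).
This imputer is hand-written because library KNN imputers work across
samples with rescaled NaN-euclidean distances, which is a different
estimator.

Covariate adjustment replaces each feature by its OLS residual on an
intercept plus the six blood-cell covariates, then re-standardizes the
residual columns so the adjusted and unadjusted branches feed
identically-scaled matrices to the CCA (the canonical correlation is
scale-invariant but the similarity normalization is not). Missing phenotype
values are dropped pairwise per analysis, never imputed.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: a
standard-normal latent factor z per subject; log-intensities
baseline + β_j·z (planted features only, β magnitudes uniform in a
configured range with random sign) + linear effects of 6 standard-normal
covariates + Gaussian noise; intensities exponentiated (log-normal raw
scale); metabolites multiplied by a per-run-day log-normal batch factor —
which makes run-day median normalization exactly the right correction — and
masked missing completely at random; phenotype γ·z + covariate contribution
+ noise. Clinical labels derive from the same latent factor: FEV₁% is a
rank-preserving map of the phenotype onto 20–120; FEV₁/FVC increases with z
(obstruction lowers ratio and flow together) squashed into (0, 1.2); percent
emphysema is a softplus of −z (nonnegative); binary indicators are Bernoulli
with logit proportional to −z.

What passing tests show — and what they do not: the generator produces
linear single-factor signal with homoscedastic noise and MCAR missingness.
Real cohorts have correlated pathway structure beyond one factor,
intensity-dependent missingness, and non-Gaussian tails; recovery results
here demonstrate correctness of the machinery, not expected performance on
any real cohort. The recovery study conditions are n = 500 subjects, 60 + 60
features with 10 + 10 planted at unit loadings, noise SD 0.5, 5% missing.

## Evaluation components

Fisher's exact test on adjusted-vs-unadjusted node overlap is one-sided
(enrichment) over the universe of features that entered the CCA after
filtering — only those could appear in either network. Per-feature
significance uses the dual rule |r| > 0.15 **and** BH-adjusted p < 0.001.
GOLD grading follows the standard spirometry thresholds exactly (boundary
values classified by the ≥ conditions; PRISm = FEV₁ < 80 with ratio ≥ 0.7);
emphysema bins are
[0,5) / [5,10) / [10,20] / (20,∞), with 5 and 10 assigned upward and 20
kept moderate so ">20%" is strict. Subgroup PC1 differences use one-way
ANOVA; pairwise contrasts use Tukey's HSD via the studentized range
(reducing to the pooled t-test for two groups).

## Problem sizes and numerical defaults

Tests and the acceptance script run the full pipeline at n = 500, p = 60+60
with 50 subsampling replicates and 10 CV repeats, completing in a few
minutes on one CPU; defaults scale to thousands of features at the cost of
proportionally longer similarity construction. Solver tolerances: weight
change < 1e−6 (max 200 iterations), projection feasibility 1e−10,
tie-collapse 1e−6 relative, monotonicity slack 1e−4 relative. Degenerate
inputs fail loudly: zero-variance features, all-zero similarity, empty
trimmed networks, rank-deficient covariate designs and all-flagged outlier
cohorts raise errors naming the offending objects.

## Known limitations

Two omics blocks only; continuous phenotypes only; the unadjusted branch's
ρ increases monotonically under trimming on synthetic data, so its selected
network concentrates on a small hub core rather than the full planted module
(mirroring the star-topology contrast seen in real sensitivity analyses);
module extraction assumes the max-normalized similarity scale, so cut
heights are not transferable to unnormalized matrices.
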