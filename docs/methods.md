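# Methods

This note records the models, estimators and numerical conventions the
package implements, the open design choices it had to make, and what its
synthetic-data tests do and do not demonstrate about real data.

## Shape data and superimposition

A landmark dataset is a set of specimen configurations in R³ with named
curves (semilandmarks with fixed endpoints), bilateral left/right pairs,
designated midline landmarks, and a missingness mask. Curves digitised with
oversampling are resampled to equal arc-length spacing on the piecewise
linear path, endpoints preserved exactly.

**Missing landmarks** are completed in two stages. Reflected relabeling:
the specimen is mirrored across its midsagittal plane (total-least-squares
plane through the present midline landmarks, i.e. the smallest right
singular vector of the centered midline block), bilateral labels are
swapped, the mirrored copy is rigidly superimposed (rotation + translation,
no scaling) on the original using all landmarks present in both, and a
missing landmark is copied from its partner's mirrored position. Remaining
cells are imputed by iterative low-rank SVD (EM-style PCA) on the flattened
specimen-by-coordinate matrix; the rank is chosen by held-out reconstruction
error on a deterministic 5% of observed cells (a simple automatic
relevance rule), configurable to a fixed integer. Fewer than three present
midline landmarks disables reflection for that specimen with a logged
warning. Provenance (reflection vs low-rank) is recorded per filled cell.
An inclusion-validation simulation masks cells in complete specimens,
imputes, and compares the consensus displacement when imputed specimens are
included versus dropped; ties count toward inclusion so that the
zero-missingness case is trivially "inclusion preferred".

**GPA.** Specimens are centered, scaled to unit centroid size, and rotated
to the running consensus by orthogonal Procrustes with reflections excluded
(det +1 enforced; anatomical landmarks are chirally labeled). With sliding
enabled, each curve semilandmark moves along its local tangent (central
difference of its curve neighbours) by the tangential component of its
offset from the consensus — the Procrustes-distance sliding criterion — and
configurations are re-projected to shape space. Sliding runs during the
first 10 iterations only: each slide perturbs the consensus, so unlimited
sliding keeps the consensus update from settling below the tolerance;
afterwards plain GPA iterates to convergence (consensus change < 1e-8,
max 100 iterations). Aligned specimens keep unit centroid size;
`tangent_coordinates()` provides the orthogonal tangent-plane projection
for Euclidean multivariate analysis. The Procrustes distance used
throughout is the partial Procrustes distance: the residual norm after
centering, unit-size scaling and optimal rotation, `sqrt(2 − 2 Σσ̃)` with
the smallest singular value sign-corrected to exclude reflections.

**Species consensus** is the arithmetic mean of aligned specimens per
species, then symmetrized by averaging with its mirrored, pair-relabeled
reflection; the averaged midline lands exactly on the fitted plane, so the
output is an exact fixed point of the reflection (bilateral symmetry to
machine precision).

## Morphospaces

pPCA uses the Brownian tip covariance `C` from the tree: the ancestral mean
is the GLS root estimate `a = (1'C⁻¹1)⁻¹ 1'C⁻¹X`, the evolutionary
covariance `R = (X−1a')' C⁻¹ (X−1a')/(n−1)` (divisor n−1, matching the
standard pPCA formulation), and scores are `(X−1a')V`. Loading columns are
sign-fixed so each column's largest-magnitude entry is positive. Parallel
analysis permutes columns independently (`n_perm` ≥ 100, default quantile
0.95 — the cited stopping rule does not state a quantile) and retains axes
while the observed eigenvalue exceeds the permuted quantile at the same
rank, stopping at the first failure; with a tree, permutation acts on the
GLS-whitened rows `C^{-1/2}(X−1a')` so the null respects phylogenetic
correlation (permuting raw rows instead is available by passing no tree).
Per-axis absolute variation is the sequential (type-I) sum of squares from
regressing the full coordinate matrix on the score columns, over the total
sum of squares; for standard-PCA scores this equals eigenvalue/trace
exactly. Scores destined for OU model fitting are multiplied by 100 purely
to keep estimated rates away from numerical underflow; the shift-search
ranking is scale-invariant by construction (see pBIC below).

## Disparity through time

Subclade disparity is the mean pairwise partial Procrustes distance.
The DTT curve is evaluated at every internal-node age (relative time), with
the just-after-divergence convention: a lineage crosses age t if its branch
spans `t_start ≤ t < t_end`. The root is reported at time 0 with value 1
(whole-clade disparity normalized to itself) and time 1 carries the terminal
singletons (value 0). The MDI is the trapezoidal integral of observed minus
the median simulated curve over the full [0, 1] range (a truncation
fraction is configurable; full range is the default). Null curves come from
multivariate BM simulated directly in the 3k-coordinate space with the ML
rate matrix `R̂ = (X−1a')'C⁻¹(X−1a')/n` (eigenvalues clipped at zero) — the
simulation therefore reproduces the full-shape-space analysis rather than a
PC-reduced one. The one-sided p counts simulated MDIs at or below the
observed (ties as lower; conservative). p lies on the 1/n_sim grid;
default n_sim is 1000, tests and the acceptance script use 100.

## Tanglegram and tip displacement

The morphology dendrogram is UPGMA (scipy average linkage) on the pairwise
Procrustes distance matrix, node heights = half the merge distance, so
cophenetic distances reproduce ultrametric inputs exactly; ties resolve by
scipy's deterministic lowest-index merge. Untangling minimizes the sum of
squared differences in matched tip positions over child-order rotations of
both structures: instances with ≤ 14 internal nodes are solved by joint
enumeration (exact), larger ones by alternating exact one-sided interval
dynamic programming until no improvement (the objective never increases).
"Vertical displacement" is the absolute rank difference of a tip between
the two post-untangling orders — the reading under which "same position →
displacement 0" is literally true; per-species pairwise-inversion counts
are also reported as a secondary statistic. The null test repeats the whole
pipeline on BM simulations with the plug-in `R̂` and counts null
displacements strictly below the observed.

## Shift detection (multi-peak OU)

Each trait axis j evolves independently under OU with selection strength
α_j, rate σ²_j, and a piecewise-constant optimum determined by shifts on
branches (shared support across traits; per-trait magnitudes). The root
state is pinned to the root optimum, removing the unidentifiable extra
parameter on ultrametric trees. Covariance
`V_j = σ²_j/(2α_j) e^{−α_j d}(1−e^{−2α_j t})` with t the MRCA depth and d
the patristic distance; a shift on branch s moves tip i's mean by
`β_{sj}(1 − e^{−α_j (T − t_start(s))})` when s is ancestral to i (the
telescoped per-branch design).

The search: (1) per-trait no-shift OU fits give an initial shared α
(geometric mean); traits are whitened by the Cholesky factor of the OU
correlation at that α, the whitened intercept is projected out, and a
multi-task lasso path (50 penalties, four decades) over all branch
predictors proposes supports with shared sparsity across traits. Supports
up to `max_shifts` (50 full-tree / 20 subclade, the published caps) are
kept; every branch the path ever touched is also proposed as a singleton
(the path tends to bundle spurious branches with real ones); sister pairs
are pruned (jointly unidentifiable with a root-state change, higher node id
dropped). (2) Each candidate is refit by ML — per-trait α by bounded
profile search on `[1e-6, 50/T]` (beyond 50/T regimes are effectively
instantaneous), optima by GLS, σ² profiled — and scored; after scoring, a
backward-elimination pass from the best candidate drops shifts while the
criterion improves. Ties break toward fewer shifts. The search is
deterministic given data and settings.

**pBIC.** The default criterion is
`pBIC = −2 logL + 3p log n + 2K log(2n−3) + Σ_j log det(I_j)`,
where K shifts are charged a placement term over the 2n−3 candidate
branches, 3p covers α, σ² and the root optimum per trait, and `I_j` is the
GLS information of the shift design for trait j **measured in stationary-SD
units** (`U' V0⁻¹ U / (2α)` at unit σ²): measuring optimum changes in
stationary standard deviations makes the penalty — and hence model ranking —
invariant to rescaling the scores, as it must be given the ×100 convention.
A candidate is discarded as unidentifiable when any trait's information
matrix has an eigenvalue below 1 (the shift magnitude cannot be estimated
to within one stationary SD; in practice this rejects single-tip "shifts"
that are outlier tips, the known failure mode of flat-prior Laplace
penalties). A trait whose fitted α collapses to the BM limit (αT < 5e-3)
has unidentifiable optima; it is refit shift-free with its optimum changes
pinned at zero and contributes no shift information. Plain BIC
(`df = 3p + K(1+p)`) is the fallback criterion. Behavioural validation:
on no-shift OU data the pBIC search returns the empty configuration in
> 90% of replicates and is never less sparse than BIC on aggregate; a
planted shift of 4 stationary SDs on an early branch is recovered (exact or
adjacent) in ≥ 90%.

**Bootstrap support** is parametric: simulate from the fitted shifted-OU
model, rerun the full search, report the per-branch inclusion fraction;
0.7 is the conventional well-supported cutoff.

## Multivariate model comparison

BM fits in closed form (matrix-normal ML; k = p + p(p+1)/2). EB transforms
each branch segment by `∫ e^{rt} dt` with r ∈ [−10/T, 0] optimized by
bounded scalar search, r = 0 evaluated explicitly so BM nests exactly
(k = BM + 1). OU1 carries full symmetric selection (A) and rate (R)
matrices, assembled in the eigenbasis of A
(`Block(i,j) = e^{−A(T−t)} [∫₀ᵗ e^{−Av} R e^{−Av} dv] e^{−A(T−t)}`), root
state at the optimum, optima profiled by GLS; Nelder–Mead over the two
Cholesky factors with deterministic restarts, and a near-zero-A candidate
guarantees logL(OU1) ≥ logL(BM) (k = p + p(p+1)). Multi-peak OU accepts a
regime painting (from a shift configuration or a stochastic map, including
within-branch change points) in two structures: **diagonal** (default;
per-trait independent α, σ², free root state; k = regimes·p + 3p — the
structure whose count reproduces the published 12-regime, p = 3 count of
45) and **symmetric** (full A and R, root at its regime's optimum;
k = regimes·p + p(p+1), reproducing the published ecological-model counts
21/30/32/44). The published 16-regime, p = 4 count of 80 does not decompose
under either structure (76 or 84); the package reports its own counts and
flags the discrepancy rather than forcing agreement. AICc uses
n = tips × traits — the convention validated against all eight published
(logL, k) → AICc mappings to ±0.01. Regimes with no descendant tips are
flagged (optima unidentifiable) and handled by least squares.

SIMMAP: the Mk rate matrix (ER default; SYM/ARD available) is fitted by ML
with the pruning algorithm, root prior = stationary distribution of Q (the
minimal choice where no prior is stated); joint node states are drawn
conditionally from the pruning partials and within-branch histories by
uniformization bridges (jump count from the truncated Poisson series, jump
chain by backward DTMC sampling, virtual jumps dropped). Map ensembles are
summarized as median (min, max) of logL/AICc, with ΔAICc against the best
median.

## Synthetic data: what it emulates, and what it does not

Trees are pure-birth (Yule), rescaled to unit depth to match the
relative-time axis of DTT; empirical trees' rate variation and extinction
are out of scope. Landmark datasets are a bilaterally symmetric template
(three midline anchors, a midline curve, three paired fixed landmarks and a
paired curve per side; k = 9 + 3·semilandmarks, 30 by default) plus
multivariate-BM deviations; deviations are predominantly symmetric (an
asymmetry fraction, default 0.2, of the raw deviation is left
unsymmetrized) to emulate near-symmetric organisms — this is what makes
reflected relabeling informative, mirroring zygomatic/bulla-style damage on
one side only. Each specimen receives a uniform random rotation, a
translation, and a log-normal(0, 0.1) scale, exercising GPA nuisance
removal; missingness is Bernoulli per landmark slot with both-members-of-a-
pair collisions resolved by unmasking the right member (at realistic rates
≤ 5.5% this matches the nominal rate to binomial error). Shifted-OU traits
are simulated by exact branch-wise transition sampling; optional
adaptive-zone shifts can be expressed in landmark data along fixed
orthonormal deformation directions.

Study conditions for the operating-characteristic tests: 64-tip trees;
30-landmark shapes at BM rate 0.001 for the MDI test; α = 3 (phylogenetic
half-life ≈ 0.23 tree depths), σ² = 1, p = 2 axes for shift detection,
with planted shifts on the earliest branch subtending 6–16 tips — a shift
must predate the present by enough time to express, and shifts on very
shallow branches are intrinsically weakly identifiable (hence also the
parent/child adjacency tolerance in recovery scoring). The tanglegram null
calibration uses 9-landmark shapes (27 coordinates) so the coordinate
dimension stays below the species count, the regime of the empirical
datasets this pipeline targets (≈ 200 species versus ≈ 90 coordinates);
when the dimension approaches or exceeds the tip count, the plug-in rate
matrix is rank-deficient and its eigenvalue spread makes the Brownian null
mildly anticonservative — a property of the plug-in parametric bootstrap
itself, not of this implementation. Replicate counts (50 meta-replicates
for DTT calibration, 40 for the tanglegram, 100 for shift detection in the
test suite; 30/30/60 in the acceptance script) were chosen to bound
Monte-Carlo error at these problem sizes.

Passing these tests shows the estimators and tests are correctly
implemented and calibrated under their own model assumptions at desk scale;
it does not establish robustness to empirical complications (measurement
error, within-species variation beyond the simple model, tree
misspecification, non-Gaussian shape variation).

## Numerical conventions and degenerate inputs

Identical shapes give zero total disparity → DTT raises rather than divide
by ~machine noise (threshold 1e-6 on the mean pairwise distance). OU
factorizations are cached per (tree, α) since the profile search revisits a
shared α grid. GLS systems use Cholesky factorizations with tiny ridge
terms (1e-10 × mean diagonal) only where full OU block covariances may be
near-singular. The p-value conventions differ deliberately between tests:
MDI counts ties as "lower" (conservative), tip displacement counts strictly
lower, both as defined. All generators and stochastic procedures take
explicit integer seeds; identical seeds give byte-identical outputs,
including Newick serialization.

## Known limitations

Single-trait-block analyses only (no mosaic partitioning); no measurement
error or intraspecific sampling models in the fits; shift detection assumes
independent traits given the shared support (cross-trait covariance is
handled only in the model-comparison module); untangling is exact only for
small trees, heuristic (though monotone) beyond; the Mk fitter assumes a
stationary root prior; pBIC's constant structure follows the published
description of the phylogenetic BIC but was validated behaviourally rather
than against the original implementation.
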