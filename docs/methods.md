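# Methods

## Model

For one gene, let `y ∈ R^n` be normalized expression over `n` spots with
coordinates `s_i ∈ R²`, `Π ∈ R^{n×K}` the per-spot cell-type proportions
(rows on the simplex; one-hot at single-cell resolution), and `X ∈ R^{n×p}`
fixed-effect covariates (default: an intercept). The linear mixed model is

    y = X β + Σ_k π_k ⊙ γ_k + ε,
    γ_k ~ N(0, τ_k K),   ε ~ N(0, σ² I),   independent across k,

giving `Cov(y) = V = Σ_k τ_k Σ_k + σ² I` with `Σ_k = diag(π_k) K diag(π_k)`.
The kernel `K_ij = κ(‖s_i − s_j‖)` is Gaussian `exp(−d²/2ℓ²)` by default
(Laplacian and Matérn-3/2 available). Because every quantity downstream
depends on the coordinates only through pairwise distances, all reported
statistics, p-values and variance decompositions are invariant to rigid
rotations and translations of the section — verified to 1e-10 in tests.

Assumptions worth stating plainly: Gaussian errors with a *common* residual
variance across spots; composition treated as known (deconvolution output);
independence of the K cell-type effects; and a shared kernel across cell
types. The normalization below is what makes the homoskedasticity
assumption tenable on real count data.

## Normalization

`normalize_counts` defaults to analytic Pearson residuals under a
depth × gene negative-binomial null: `z = (c − μ̂)/sqrt(μ̂ + μ̂²/θ)` with
`μ̂_gi = (row total · column total)/grand total`, `θ = 100`, clipped at
±√n. Spots aggregate very different numbers of cells/reads; under a
log-size-factor transform their noise variance scales roughly inversely
with depth, and a homoskedastic spatial test then reads the extra noise of
shallow spots — which is coupled to their noisier composition estimates —
as signal. Pearson residuals equalize the variance per spot by
construction. The log transforms (`log_cpm_median`: count divided by
spot-total/median-total size factor, then log1p; `log1p_size_factor`:
counts-per-10k log1p) are retained as options; with them, type-I error at
desk scale inflated from ~0.05 to ~0.08–0.10 in our null simulations.

## Score tests

Stage 1 tests `H0: τ_1 = … = τ_K = 0`. Under H0 the model is OLS; with
`P̂ = (I − X(XᵀX)⁻¹Xᵀ)/σ̂²` and target `Σ_T = Σ_k Σ_k = K ∘ (ΠΠᵀ)`, the
score statistic is `Q = ½ yᵀ P̂ Σ_T P̂ y`. Its p-value comes from a scaled
chi-square `κ χ²_ν` matched to the *exact* finite-sample moments of the
studentized form `T = rᵀΣ_T r / σ̂²` (with `r` the OLS residuals,
`ν_res = n − p`): writing `A = MΣ_T M` for the residual projector `M`,

    E[T] = tr A,
    Var[T] = 2 ν_res/(ν_res+2) · (tr A² − (tr A)²/ν_res),

which follow from `T/ν_res` being a quadratic form in a uniform vector on
the residual sphere. These coincide with the usual efficient-information
Satterthwaite construction up to the `ν_res/(ν_res+2)` factor, which
matters at small n. The same factor is applied to the stage-2 information
(exactness there is only asymptotic; calibration is verified by
simulation). `κ = Var/(2E)`, `ν = 2E²/Var`, `p = P(χ²_ν > T/κ)`.

Stage 2 tests `H0: τ_k = 0` per cell type among the stage-1 discoveries.
The null keeps the other K−1 components: constrained REML (Fisher scoring
with expected information, step-halving, non-negativity projection,
relative log-REML tolerance 1e-8, 200-iteration cap; non-convergence falls
back to the OLS null with a warning, which is conservative because
unabsorbed nuisance variance inflates σ̂²). The statistic is
`Q = ½ yᵀ P̂ Σ_k P̂ y` with `P̂` built from the fitted null covariance, and
the Satterthwaite variance is the efficient information — the τ_k block of
the information matrix adjusted for all fitted variance parameters.

An exact reference method (`method="davies"`) inverts the characteristic
function of the weighted-chi-square null (Imhof's integral). For OLS nulls
it evaluates the scale-free studentized form `P(Σ_i (λ_i − T/ν_res) w_i −
(T/ν_res) Σ_j w_j > 0)` (λ_i the eigenvalues of A, w iid χ²₁), which
accounts for the estimation of σ² exactly; with REML-fitted nuisance
components it uses the plug-in weights. Satterthwaite and Davies p-values
agree within a factor ~1.5 down to p ≈ 1e-4 on small instances and the
dense-matrix oracle agreement is 1e-8 (both asserted in tests).

## Bandwidths and aggregation

The anchor bandwidth is `ℓ0` = median nonzero pairwise spot distance. For
n < 1000 spots the default is 5 bandwidths geometric in `[ℓ0/4, ℓ0]`,
with per-bandwidth p-values combined by the Cauchy rule
`p = ½ − arctan(mean tan(π(½ − p_i)))/π`, which is insensitive to the
strong dependence between bandwidths. For larger n a single `ℓ0` is used.
The grid is deliberately capped at `ℓ0`: beyond the median distance a
Gaussian kernel is nearly constant over the tissue, `Σ_T` degenerates
toward `ΠΠᵀ`, and the statistic stops measuring spatial structure and
starts measuring association with (noisily estimated) composition — in
null simulations those bandwidths alone pushed type-I error to ~0.07 even
with exact p-values. Patterns at domain scale live below `ℓ0`, so nothing
of scientific interest is lost. Kernel eigendecompositions are computed
once per bandwidth and shared across genes; tests assert equality with the
naive dense computation.

Multiple testing: Benjamini–Yekutieli (valid under arbitrary dependence)
across all genes at stage 1; at stage 2, BY within each cell type across
the utSVG family (the alternative — one adjustment across the whole
utSVG × K matrix — is a defensible reading; per-cell-type was chosen so
each cell type's discovery list is self-contained).

## Variance decomposition

`estimate_components` fits all K+1 components of the full model by the same
constrained REML and reports shares `τ̂_k tr(Σ_k)/n` (each component's
average marginal variance per spot) against their total plus `σ̂²`. The
normalization of the shares is a package choice; the alternative of
reporting raw `τ̂_k` ignores that a rare cell type's component contributes
little marginal variance even at large τ. Boundary truths (τ = 0) estimate
to exactly 0 with probability well above 0.4, the expected half-mass of the
boundary REML estimator.

## Synthetic data

The generators emulate two single-cell-resolution study designs on the
unit square, then aggregate to spots:

* cells from a homogeneous Poisson process (count ~ Poisson(N), locations
  uniform) with N = 10,000 (design family `sim1`) or 4,000 (`sim2`);
* circular spatial domains: `sim1` has background D1 plus two discs D2/D3
  centered at randomly chosen cells with radii U(0.1, 0.5), overlap
  resolved toward the smaller radius; `sim2` has one disc SD with radius
  U(0.2, 0.4) against background D;
* three cell types drawn iid per cell — scenarios (15/15/70), (30/30/40),
  (45/45/10) for `sim1`; (10/30/60) for `sim2`; `sim1_alt3` instead draws
  domain-conditional pairs ({1,2}, {2,3}, {1,3} at 50/50);
* 1000 genes per run with negative-binomial counts, mean μ = 1 and
  dispersion φ (variance μ + μ²/φ; φ ∈ {0.7, 1.5} are the study values,
  larger φ = less noise). Design-specific fold changes on the mean define
  markers (uniform within-type elevation), domain SVGs, and within-type
  ctSVGs in groups of fold change 4 / 2 / 0.5 / 0.25; a fold change of 0 is
  a point mass at zero. `sim1_alt2` uses complementary within-type patterns
  (×2 in D1 and 0 in D2 for type 1, mirrored for type 2, type 3 flat at the
  baseline mean μ = 1) so the combined expression is spatially flat — ctSVG
  but not SVG;
* spot aggregation on a regular grid (0.03125 → 1024 cells at full `sim1`
  scale, 0.05 → 400 for `sim2`): counts summed, spot coordinate = centroid
  of member cells, composition = member-type fractions; empty grid cells
  are dropped (they have no cells, hence no coordinates). Count totals are
  conserved exactly.
* a misspecification arm replaces the composition with 4 fake types drawn
  Dirichlet(1,1,1,1) per spot, emulating a badly wrong deconvolution.

What the generators do *not* emulate: platform-specific spot geometry
(hexagonal arrays, varying capture efficiency), gene–gene correlation,
zero inflation beyond NB, segmentation errors, or real deconvolution noise
(the misspecification arm brackets it from the pessimistic side). Passing
tests therefore demonstrate correctness and calibration of the statistical
machinery under the stated generative model, not robustness to every
artifact of a real assay.

Note a structural consequence of the model, visible in the synthetic runs:
a pure marker gene (uniform elevation within one cell type, no spatial
pattern) is indistinguishable from a constant draw of that type's spatial
effect, since the kernel's leading eigenvector is nearly constant. Such
genes are legitimately flagged by both stages; in real tissue this is the
behavior that surfaces marker genes with cell-type-specific patterns.

## Problem sizes and defaults

Validation runs use scaled designs chosen as the smallest sizes at which
the statistical properties are cleanly visible: `sim1` scaled to ~2500
cells / ~256 spots (grid 0.0625) for calibration and stage-1 power, full
`sim2` (4000 cells / 400 spots) for stage-2, five replicates where
orderings are compared, 700 null genes for type-I error, and n = 300 with
200 replicates for variance-component recovery. The stage-2 validation
uses the single rule-of-thumb bandwidth and a balanced subsample of 25
genes per fold-change group per cell type; per-gene REML over every
bandwidth and gene adds runtime but no information at these scales.
Degenerate genes (zero residual variance) are assigned p = 1; p-values are
floored at 1e-300; composition rows are renormalized on input when within
1e-3 of 1 and rejected otherwise.

## Known limitations

* Gaussian response only; raw-count generalized versions are out of scope.
* Power depends on deconvolution quality; composition error biases stage-2
  attribution even where stage-1 calibration survives (the
  misspecification analysis shows the latter, not the former).
* The overall-test target weights all cell types equally; a weighted
  combination could gain power when composition scales differ wildly.
* No uncertainty intervals on variance shares (point estimates only).
* REML at n spots costs O(n·r²) per iteration after the one-off kernel
  eigendecomposition (r = numerical kernel rank); very large n would need
  the single-bandwidth default and benefits from low-rank structure, but
  no further approximation is implemented.
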