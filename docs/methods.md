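# Methods

This note documents the statistical model behind `pcgmm`, the choices made
where the design was genuinely open, and what the simulation-based tests do
and do not establish.

## Problem setting

Multivariable *cis*-Mendelian randomization asks which of several related
risk factors (e.g. body-mass index and type-2-diabetes liability, or gene
expression across tissues) carries the causal pathway from a single drug
target gene to a disease outcome. The instruments are the genetic variants
of one gene region, summarized as per-variant marginal regression
coefficients from separate GWAS ("two-sample" summary data): a J×K matrix
β̂_X with standard errors, a length-J vector β̂_Y with standard errors, and a
J×J signed LD correlation matrix ρ estimated in a reference panel.

Two kinds of heterogeneity drive everything:

- **Phenotypic heterogeneity** (good): distinct variants in the region
  associate with different patterns of risk factors. Without it the
  genetic predictors of one risk factor are a linear combination of the
  others' (a rank reduction) and the multivariable effects are not
  identified.
- **Overdispersion heterogeneity** (bad): variants have direct effects on
  the outcome not mediated by the modelled risk factors. It leaves point
  estimation consistent but makes naive standard errors too small.

## PC dimension reduction

Variants in one region are heavily correlated, and ρ is typically
ill-conditioned, so the method instruments with principal components
rather than variants. We eigendecompose a weighted correlation matrix
Ψ_ij = ρ_ij w_i w_j with default weights w_j = Σ_k |β̂_X[j,k]| / se(β̂_Y[j])
(association strength across risk factors over outcome precision; an
outcome-weighted variant is available via `weight_mode="outcome"`), and
retain the smallest p whose cumulative eigenvalue share reaches a
threshold (99% default for data analysis; 99.99% in the simulation study).

With loadings Λ (J×p) and Gram matrix S = Λ'ρΛ, the PC-scale multivariable
coefficients and their covariances are

    β̃_Y = S⁻¹Λ'β̂_Y,            Ω_YY = S⁻¹Λ' D_Y ρ D_Y Λ S⁻¹,
    β̃_X[:,k] = S⁻¹Λ'β̂_X[:,k],  Ω_XX[k,l] = c_kl · S⁻¹Λ' D_Xk ρ D_Xl Λ S⁻¹,

where D are diagonal SE matrices and c_kl is the phenotypic correlation
between risk factors k and l (user-supplied; identity off-diagonals by
default). This uses the standard large-sample result that marginal GWAS
estimates have covariance ρ_jk·se_j·se_k within one sample, scaled across
traits measured in the same sample by their phenotypic correlation.

**A conditioning caveat validated empirically:** the covariance model holds
only for components whose LD eigenvalue is large relative to the 1/n
sampling noise of the correlation structure. Retaining near-null
directions (an over-aggressive variance threshold on an ill-conditioned
matrix) inflates the true sampling variance of the transformed
coefficients by an order of magnitude relative to the formula. The
variance formula is therefore tested against the empirical replicate
covariance of the simulator (agreement within 10% in the healthy regime),
and the transform refuses Gram matrices with condition number above 1e12.

## CUE-GMM estimation with overdispersion

The moment vector is g(θ) = β̃_Y − β̃_X θ with model-implied covariance

    Ω(θ, κ²) = Ω_YY + Σ_{k,l} θ_k θ_l Ω_XX[k,l] + (κ²/n_Y) · S⁻¹Λ'ρ²ΛS⁻¹.

The last term is the exact PC-scale image of isotropic variant-scale
direct effects α ~ N(0, κ²/n_Y): marginal outcome estimates absorb ρα, so
the PC coefficients absorb S⁻¹Λ'ρα. Parameterizing by κ² (per outcome
sample size) makes the estimate directly comparable with the simulation's
generating value; κ̂² averages 0.99 when the truth is 1.

The continuously-updating estimator minimizes Q(θ, κ²) = g'Ω⁻¹g, with the
weighting re-evaluated at every θ (less weak-instrument bias than two-step
GMM). Minimization is quasi-Newton (BFGS) with the analytic gradient

    ∂Q/∂θ_a = −2(β̃_X'W)_a − 2 Σ_b θ_b W'Ω_XX[a,b]W,   W = Ω⁻¹g,

started from the inverse-variance-weighted estimate, with a derivative-free
refinement and five jittered restarts on non-convergence.

- **Unrobust fit** (κ² = 0): Q(θ̂,0) is the overidentification
  (heterogeneity) statistic, χ²_{p−K} under correct specification;
  rejection signals unmodelled heterogeneity, i.e. possible pleiotropy.
- **Robust fit**: κ̂² solves Q(θ̂, κ²) = p − K (the objective's null
  expectation), floored at 0 — a method-of-moments choice consistent with
  overdispersion affecting inference rather than estimation. The
  alternation between θ-minimization and the κ² root converges to relative
  tolerance 1e-6 (max 100 iterations). The root search is bisection on a
  whitened spectral form Q(κ²) = Σ c_i²/(1+κ²d_i), making each step O(p).

Standard errors come from the closed-form GMM curvature (β̃_X'Ω⁻¹β̃_X)⁻¹
evaluated at the plug-in (θ̂, κ̂²); a numerical-Hessian variant is exposed
via `se_method="hessian"`. Plug-in SEs ignore the sampling noise of κ̂²;
the simulation calibration (type-I error 5–9% at nominal 5% in the hardest
cell) quantifies the cost. Wald intervals use the normal quantile; 95%
default, no multiplicity adjustment.

## Conditional F-statistics

For risk factor k, phenotypic heterogeneity is tested against the rank
reduction β̃_X[:,k] ≈ β̃_X[:,−k]δ. We solve the continuously-updated GLS
fixed point δ ← argmin_d h(d)'V(δ)⁻¹h(d), h(d) = β̃_X[:,k] − β̃_X[:,−k]d,
where V(δ) is the exact covariance of h from the Ω_XX blocks, and report
F_k = q(δ̂)/(p−K+1) with q(δ̂) referred to χ²_{p−K+1}.

The fixed point — not joint minimization of q over δ — is essential: the
jointly minimized criterion is invariant to rescaling the combination
vector (q(tc) = q(c)), so its infimum detects a rank deficiency anywhere in
the coefficient matrix and is the same for every risk factor. The iterated
form keeps the statistic specific to factor k while still updating the
weighting continuously. Degrees of freedom are p moments minus the K−1
freely fitted combination coefficients; the ξ = 0 size simulation is the
calibration check for this choice. Critical values are plain χ² quantiles,
not weak-instrument-adjusted thresholds. F < 10 triggers a weak-instrument
warning, F < 1 a strong one.

## Colocalization

Evidence that two traits have distinct causal variants in the region is
itself evidence of phenotypic heterogeneity. We use Wakefield approximate
Bayes factors per variant, logABF = ½[log(1−r) + r z²] with
r = s²/(s²+se²), and enumerate the single-causal-variant-per-trait
configurations for hypotheses H0–H4 with priors p1 = p2 = 1e-4,
p12 = 1e-5 (defaults of the referenced approach). Effect priors default to
s = 0.15 (quantitative) and 0.2 (log-odds), both configurable, since case-
control inputs may warrant the larger prior. A grid scan over p12 reports
the sensitivity of the shared-variant posterior; H3/(H3+H4) summarizes
"distinct variants given both associated". Colocalization operates on
marginal (not PC-transformed) associations and assumes at most one causal
variant per trait.

## Risk-factor model averaging

With many candidate risk factors (K up to ~10 tissues), each non-empty
subset defines a sub-model β̃_Y = β̃_X[:,subset]θ + ε, ε ~ N(0, Ω_YY), with
Gaussian effect prior θ ~ N(0, σ²I), σ = 0.5 on the standardized PC scale
by default. Marginal likelihoods are closed-form Gaussians; subset priors
are p^s(1−p)^{K−s} with p = 0.1 (prior expectation of about one causal
risk factor). Enumeration is exhaustive rather than stochastic search:
exact, deterministic, and fast for K ≤ 20 (1023 models at K = 10 in well
under a second). Marginal inclusion probabilities sum model posteriors per
risk factor.

## Simulation design

`pcgmm.simulate` generates individual-level data and reduces it to summary
statistics by actual per-variant regressions (no analytic shortcut), in
two independent samples of sizes n_X (exposures) and n_Y (outcome):

    X1 = 0.2·Σ_{m=1..5} Z_m + V1
    X2 = 0.2ξ·Σ_{m=6..10} Z_m + 0.2(1−ξ)·Σ_{m=11..15} Z_m + V2
    X3 = 0.2·Σ_{m=11..15} Z_m + V3
    Y  = θ'X + Z'α + U,   θ = (−1/3, 0, 1/3)

with 200 instruments, var(V_k) = 1, cor(V_k,V_l) = 0.3, var(U) = 1,
cor(V_k,U) = 0.2, and direct effects α ~ N(0, κ²/n_Y) drawn once per
replicate (the random-effects reading of the design; no per-individual
redraw). ξ ∈ [0,1] indexes phenotypic heterogeneity — at ξ = 0 risk
factors 2 and 3 share causal instruments exactly — and κ² ∈ [0,1] indexes
overdispersion. No re-standardization of X2 is applied at intermediate ξ,
matching the stated equations. The pipeline consumes the generator's true
LD matrix (the design assumes known instrument correlations); a
`estimate_sample_ld` flag substitutes the sample estimate for sensitivity
checks. The trait-correlation input is the empirical exposure correlation
from sample 1.

**The synthetic LD stand-in.** The measured regional correlation matrix
used by the original simulation design is not distributable, so
`synthetic_ld` emulates its regime: 10 AR(1) blocks of 20 variants at
within-block decay 0.9, a uniform 0.108 between-block component, a seeded
low-rank perturbation (capped so the 15 designated causal instruments stay
mutually weakly correlated, R² ≤ 0.2, for every seed), and a spectral
truncation to effective rank 30 (tail eigenvalues carry 2e-5 of the
variance). The truncation is the essential realism ingredient: measured
regional LD is near-singular, and only a near-singular stand-in reproduces
the regime where ~25–40 components explain 99.99% of weighted variance
among 200 variants. These defaults are the package's fixed study
conditions, not tuning knobs.

What the stand-in does not reproduce: the exact correlation topology of
any real region, allele-frequency-dependent LD, or the specific ρ² density
of the measured matrix. Quantities that depend on that density — most
visibly the *size of the anti-conservatism* of the unrobust test under
overdispersion — shift with it: a denser ρ² makes ignoring overdispersion
more costly. Calibration results (test sizes near nominal, κ̂² recovery,
RMSE trends) transfer; exact inflation percentages should be read as
stand-in-specific.

## Problem sizes and reproducibility

Reference cells run 500 replicates at n_X = n_Y = 20,000 with the 99.99%
threshold — the scale used by `scripts/acceptance.py` and the calibration
tests; exploratory grids default to 200 replicates per cell. Per-cell
seeds derive from a master seed through `numpy.random.SeedSequence`
streams, so cells are independent and every run is exactly reproducible;
grid reruns with the same seed are byte-identical. Replicates whose fit
fails (singular reductions at tiny n) are counted and reported; a cell
with more than 10% failures is flagged, not fatal.

## Numerical choices

- Eigenvector sign convention: each loading column's largest-magnitude
  entry is positive (deterministic basis).
- Components with eigenvalues below 1e-12 of the leading eigenvalue are
  never retained; negative eigenvalues of Ψ are excluded from the variance
  denominator.
- PSD repair of LD matrices clips negative eigenvalues at zero and
  rescales to unit diagonal; PSD inputs pass through untouched. Inputs may
  overshoot |r| = 1 by up to 5e-3 (estimation/rounding noise) and are
  repaired rather than rejected.
- Pruning is greedy by minimum risk-factor p-value (Wald z against the
  standard normal), ties broken by position then id; the significance
  screen is strict (p < threshold). Pruning precedes screening.
- Missing summary rows are dropped, never imputed, with a logged count.
- Output TSVs print 6 significant digits so identical runs are
  byte-identical across platforms.

## Known limitations

- The overdispersion correction addresses random direct effects; directed
  (idiosyncratic) pleiotropy biases estimation and is out of scope.
- Plug-in standard errors mildly under-cover in the hardest overdispersed
  cells (simulated type-I error up to ~8% at nominal 5%).
- Conditional F-tests show mild finite-sample size inflation (~6–7% at
  nominal 5% at n = 20,000) from the estimated combination vector and
  trait correlations entering the weighting.
- Colocalization assumes a single causal variant per trait and ignores LD
  (the standard enumeration); multi-signal extensions are not implemented.
- Palindromic variants are kept with a warning; no frequency-based strand
  inference is attempted.
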