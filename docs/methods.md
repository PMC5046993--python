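# Methods

`cladescan` asks whether one focal lineage (the motivating case: the human
tip within a primate phylogeny) has undergone exceptional evolutionary
change in quantitative traits, using two complementary Bayesian
phylogenetic comparative analyses plus a simulation-based validation of the
first.

## 1. Phylogenetic prediction (PGLS + reversible-jump MCMC)

### Model

For a trait vector `y` over `n` species (log10 scale) and candidate
predictors `X` (by default log10 female body mass),

    y ~ MVN( a + X b,  sigma2 * C_lambda ),
    C_lambda = lambda * C + (1 - lambda) * diag(C),

where `C` is the Brownian covariance of the tree (`C[i,j]` = shared
root-path length) and `lambda` in [0, 1] is Pagel's transform applied to
the off-diagonal covariances. `lambda = 0` is a star phylogeny — an
ordinary independent-observations regression — and `lambda = 1` the full
tree. Applying lambda to covariances rather than literally rescaling
internal branches reproduces both limits exactly and is safe for
non-ultrametric trees; whether the original implementation also rescaled
tip branches to preserve height is not documented, so the covariance
convention is adopted and stated here.

### Priors and sampler

* coefficients and intercept: proper uniform on [-100, 100] (log10 trait
  units) — a wide proper version of a flat prior, needed so that
  reversible-jump moves have a density to evaluate;
* inclusion indicator per predictor: Bernoulli(1/2); the intercept is
  always in the model (model selection concerns predictors only);
* `lambda`: uniform on [0, 1];
* `sigma2`: Jeffreys `1/sigma2`, updated by a log-scale random walk (the
  prior cancels the Jacobian, so these moves accept on likelihood alone);
* phylogenetic uncertainty: the tree index is a parameter, resampled
  uniformly over the supplied posterior tree sample.

Moves per iteration (one of, with fixed probabilities): predictor toggle
(reversible jump), coefficient/intercept random walk, reflected random walk
on `lambda`, log random walk on `sigma2`, tree resample. The
reversible-jump birth draws the new coefficient from an independence
proposal centred on the conditional GLS estimate `(u'q)/(u'u)` with
variance `2 sigma2 / (u'u)` (whitened design column `u`, whitened residual
`q`); the uniform prior density enters the acceptance ratio explicitly
(Jacobian 1). Proposing from the wide prior itself is valid but
accepts birth moves so rarely that inclusion indicators effectively never
mix; the GLS-centred proposal leaves the posterior untouched and mixes well
(posterior inclusion ~1 and nominal CI coverage for a strong simulated
slope).

The default chain is 200,100 steps, burn-in 100, thinning 100 — 2,000
retained states. Each retained state carries one draw from the conditional
predictive normal for the held-out target tip

    mean = x_t b + c_to C_oo^{-1} (y - X b),
    var  = sigma2 (c_tt - c_to C_oo^{-1} c_ot),

with all covariance blocks lambda-scaled (diagonals untouched). The target
is removed from the fitting data, so the 2,000 predictive draws integrate
over coefficients, model composition, `lambda`, `sigma2`, and phylogeny.
No extra tip-level noise is added beyond the conditional variance: the
predictive draws describe the evolutionary expectation for the tip, which
is the published procedure as far as it is documented; this choice is the
one assumption the calibration study below tests directly.

### Outlier calls

The two-sided outlier probability defaults to a normal approximation of
the predictive draws (their normality is the user's responsibility to
inspect, e.g. by Q-Q plot; an add-one-smoothed empirical mode is
available). Per-trait selection uses Benjamini–Hochberg step-up FDR at
q = 0.10. `fdr_select` exposes a `tol` argument for inputs that are printed
roundings of underlying p-values (a two-decimal table entry of 0.02 can
represent anything in [0.015, 0.025)); `tol = 0.005` — half a printed unit
in the last place — reproduces the published eight-trait significant set
from the published two-decimal probabilities. `tol` defaults to 0 and
should stay 0 for exact p-values.

## 2. Regime shifts (multi-optimum Ornstein–Uhlenbeck)

### Model

The trait follows an OU process with mean-reversion `alpha` (1/time),
diffusion `sigma2` (trait²/time), a linear body-mass effect `beta`, and a
piecewise-constant optimum: root regime `theta0`, plus `k` shifts, each at
a position on a branch (at most one per branch). The root state is fixed
at `theta0` (non-stationary start); a stationary-root variant is a
straightforward extension but is not the default because the fixed-root
moments match the likelihood used throughout:

    E[y_i]       = sum_r theta_r w_ir + beta * mass_i
    Cov(y_i,y_j) = sigma2/(2 alpha) * exp(-alpha (T_i + T_j - 2 t_ij))
                   * (1 - exp(-2 alpha t_ij))

with regime weights `w` accumulated along each root-to-tip path
(`exp(-alpha (T - t_end)) - exp(-alpha (T - t_start))` per regime segment;
the root regime also carries the initial-condition weight
`exp(-alpha T)`). Weights sum to one for every tip and every `alpha`;
`alpha -> 0` recovers the Brownian likelihood (implemented with `expm1`
so the limit is numerically exact).

### Priors, sampler, diagnostics

Half-Cauchy priors on `alpha` (scale `1/T`, tree height `T`) and `sigma2`
(scale `var(y)/T`); uniform `beta`; Poisson(`k_mean = 1`) on the shift
count; `theta ~ Normal(mean(y), sd(y))`; shift branch uniform over
branches (one shift max per branch) and position uniform within the
branch. The published analysis delegated these scales to a data-driven
heuristic without printing them, so they are explicit, mandatory-visible
configuration here.

Reversible-jump moves: birth (uniform free branch, uniform position, theta
from a 50/50 mixture of the theta prior and a normal centred on the mean
trait value of the tips below the candidate branch — the mixture density
appears in the acceptance ratio, so the target posterior is unchanged;
prior-only proposals required tens of thousands of extra iterations to
find well-supported shifts), death (uniform over current shifts),
relocation (slide within branch, or jump to a free branch keeping theta),
plus scalar random walks. Under a constant likelihood the sampled `k`
matches the Poisson prior (chi-square check in the test-suite), which
validates the jump acceptance ratios end-to-end.

Defaults follow the published settings: two chains of 2,002,000 steps,
burn-in 2,000, thinning 1,000 — 2,000 samples per chain. Convergence is
assessed with Gelman's R (classic between/within form) on the
log-likelihood series; `combine_chains` drops an equal fraction from each
chain front — the smallest of ten candidate fractions (0, 5%, …, 45%)
minimising R — before pooling, then reports R, the truncation and the
effective sample size `n / (1 + 2 sum rho_t)` with the autocorrelation sum
truncated at the first non-positive term. The exact truncation procedure
of the original study is not documented; this grid rule is a stated
stand-in.

Shift summaries per branch (branches identified by their tip-set
bipartition string, stable across node orderings): posterior proportion of
models with a shift, mean/SD of the shift magnitude, and proportion of
positive shifts. Magnitude is `theta_new - theta_parent-regime` (the
regime just rootward of the shift), the quantity whose sign the
directionality summary uses; magnitude relative to the grand mean is the
other defensible convention and is not used. The decision rule for the
focal branch: at least 20% of models place a shift there and at least 95%
of those shifts agree in sign.

## 3. Synthetic data and the validation study

The generator emulates the structure of the real study table: ~50 species;
log10 body mass evolving by BM (root 3.0 log10 g, rate 0.25 — a
primate-scale spread); traits as `beta * mass + BM/OU noise`; per-cell
missingness; a designated target tip. Random trees are pure-birth with the
terminal branches extended by the waiting time to the next event (so no
zero-length terminals) and rescaled to height 1. The target tip defaults
to the tip whose terminal branch is closest to 10% of tree height,
emulating the human branch's share of the primate tree depth.

The rate-multiplier study mirrors the published validation: 100 datasets
of constant-rate BM (`sigma2 = 1`, root 0, mass present with `beta = 0`)
and 150 datasets with an independent Uniform(1, 4) multiplier on the
*variance* of the target's terminal branch (numerically identical to
multiplying its length, under BM). Each dataset runs the prediction stage
and the target is scored an outlier when its simulated value falls outside
the central 95% of the predictive draws. One uniform draw per dataset is
the only reading of "rate varying continuously" that produces a smooth
detection-versus-rate curve.

What the generator does *not* emulate: measurement error and within-species
variance, unequal per-cell animal counts, non-ultrametric trees, correlated
missingness, and multi-trait covariance. Passing tests therefore certify
the statistical machinery under the stated generative models, not the
biology of any particular dataset.

## 4. Scaled-down problem sizes

The default test and validation runs use deliberately reduced chain
lengths, chosen as the smallest sizes at which the pilot chains were
visibly converged, and stated here as the package's own study sizes:

* validation study: 100 null + 50 alternative datasets, 20,100-step chains
  (200 predictive draws each);
* calibration: 500 replicates on a 15-tip tree, 4,100-step chains, with a
  95% ± 3% coverage band;
* OU shift recovery: 35 tips, 60,000-step chains. Shorter (25–30k) chains
  were not reliably converged for this problem — the shift-present and
  shift-absent explanations are well-separated modes;
* full published settings remain the library defaults.

## 5. Numerical and degenerate-case choices

* Cholesky factorisations are cached per (tree, lambda) or per alpha;
  coefficient moves update whitened residuals in O(n).
* Predictive variances that round off slightly negative are clamped to 0
  (warning above 1e-8 relative).
* Zero predictive spread makes the outlier probability degenerate (1 if
  the observation equals the mean, else 0, with a warning).
* A trait is skipped in the all-species scan (with a log entry) when a
  hold-out would leave fewer than 3 species.
* The empirical-logit meta-analysis uses the +0.5 continuity correction so
  species with zero outlier traits keep a finite transform; its tail
  probability is one-sided (the hypothesis is an *excess* of outliers).
* Gelman's R raises on constant chains (zero within-chain variance); the
  ESS estimate is capped at the series length.

## 6. Known limitations

* Only optimum shifts are modelled; `alpha` and `sigma2` are global
  (no rate regimes), and traits are analysed one at a time.
* The OU stage accepts a single tree; phylogenetic uncertainty is handled
  only in the prediction stage.
* Detection power for optimum shifts depends strongly on the covariate
  structure: a lone displaced tip on a long terminal branch without a
  strong covariate is genuinely absorbable by a high-variance, low-alpha
  fit, and no sampler fixes that — it is a property of the model.
* The FDR worked example depends on two-decimal published inputs; with
  exact p-values the `tol` device must not be used.
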