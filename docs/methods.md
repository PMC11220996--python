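# Methods

## The model family

`stcar` fits Bayesian Poisson models to counts observed on a fixed set of
`n` neighbouring areas over `T` consecutive years. For area `i` and year
`t`,

    Y_it ~ Poisson(mu_it),
    log mu_it = x_it' beta + log n_it + psi_it,

where `n_it` is a known population offset and `psi_it` a space-time random
effect. Spatial structure enters through a symmetric binary adjacency
matrix `W` and the Leroux conditional-autoregressive (CAR) prior, whose
precision matrix

    Q(W, rho) = rho (W_d - W) + (1 - rho) I

interpolates between independence (`rho = 0`) and the intrinsic CAR
(`rho = 1`, improper). Under this prior each area's effect, conditionally
on the others, is Gaussian with mean
`rho sum_j w_ij phi_j / (rho d_i + 1 - rho)` and variance
`tau2 / (rho d_i + 1 - rho)`. The same machinery applied to the path graph
`Z` over years (`z_ij = 1` iff `|i - j| = 1`) gives the temporal prior.

Four decompositions of `psi_it` are implemented (canonical names follow
the CARBayesST convention; the SPLTM/SPAM/STSM/TMS acronyms are accepted
aliases):

| variant     | psi_it                                           | blocks |
|-------------|--------------------------------------------------|--------|
| `linear`    | `w1 + phi_i + (w2 + theta_i)(t - tbar)/T`        | two CAR(W) fields (intercepts, slopes), `tbar = (T+1)/2` |
| `anova`     | `phi_i + theta_t + gamma_it`                     | CAR(W) + CAR(Z) + iid N(0, tau2_int) interaction (Knorr-Held ANOVA) |
| `separable` | `phi_it + theta_t`                               | one CAR(W) field per year (variance `tau2_t` each) + CAR(Z) trend |
| `ar`        | `phi_it`                                         | `phi_1 ~ N(0, tau2 Q^-1)`, `phi_t | phi_{t-1} ~ N(rho_T phi_{t-1}, tau2 Q^-1)` |

Priors: vague normal N(0, 1e5) for `beta` and `omega` (a proper stand-in
for a flat prior that changes nothing at these data scales), inverse-gamma
IG(1, 0.01) for every variance (the convention of the reference software
family for these models; configurable), Uniform(0, 1) for every `rho`.
Density evaluation at `rho = 1` is refused (the intrinsic limit is
improper); samplers move `rho` on the logit scale so the boundary is never
reached.

## Sampling

A Metropolis-within-Gibbs sweep updates: fixed effects (block random-walk
Metropolis, initialised at the Poisson GLM MLE with proposal scales from
its standard errors), every latent block (single-site random-walk
Metropolis with the CAR full conditional supplying the prior term), the
variances (exact inverse-gamma Gibbs using `u'Q u = rho u'(W_d - W)u +
(1 - rho) u'u`), and the `rho` parameters (logit-scale Metropolis with the
determinant evaluated as `sum_k log(rho lambda_k + 1 - rho)` from the
precomputed eigenvalues of `W_d - W`).

Single-site updates are executed *chromatically*: the graph is greedily
coloured, and all sites of one colour — pairwise non-adjacent, hence with
mutually independent full conditionals — are proposed and accepted
simultaneously. For the `ar` field the colouring is (spatial colour) x
(year parity), since the prior couples sites only within a year or at lag
one. This is exactly the single-site kernel, executed as a handful of
vectorised operations per sweep, which is what makes 120,000-iteration
runs affordable on one core.

Proposal scales are sitewise informed — `f / sqrt(likelihood curvature +
prior precision)`, with the likelihood curvature `sum exp(eta)` over the
cells a site touches — and the per-block factor `f` adapts during burn-in
toward 40–50% acceptance for scalar updates (25% for the fixed-effect
block), Roberts–Rosenthal style with decaying steps. Kernels freeze at the
end of burn-in, so the retained chain has the exact posterior as its
stationary distribution. Defaults mirror the reference analysis: 120,000
iterations, 20,000 burn-in, thinning 10, one chain; `run_chains` plus
`diagnostics` (split-Rhat, ESS via arviz) support multi-chain checks,
which single-chain practice cannot provide on its own.

One master seed derives independent per-block generator streams
(`numpy.random.SeedSequence.spawn`), making runs bit-reproducible.

**Identifiability.** The additive decompositions confound block means with
the intercept. After each sweep structured blocks are re-centred to mean
zero and the subtracted mean is added to the intercept (`linear`: `phi`
into `omega_1`, `theta` into `omega_2`; `separable`: per-year field means
into `theta_t`, then the `theta` mean into the intercept), leaving the
linear predictor — and hence the likelihood — exactly unchanged. The
re-centring move perturbs the prior only in the near-flat intercept
direction. `ChainConfig(recenter=False)` disables it; that is the correct
setting for kernel-validation runs with the likelihood switched off, where
no confounding exists and the chain must reproduce the joint prior exactly
(the prior-recovery tests do this, and the sampled `tau2` and `rho`
marginals match IG(1, 0.01) and Uniform(0, 1) by Kolmogorov–Smirnov).

Variance Gibbs updates use the full block dimension `m` in the shape
`a + m/2` (CARBayes convention). The `separable` variant keeps one spatial
variance per year; `pooled_spatial_variance=True` pools them for short
panels. A non-finite linear predictor aborts the run naming the offending
block.

## Synthetic data

The generator emulates an FAO-style continental panel: 54 areas x 20 years
= 1080 cells. Counts and populations are recorded in **millions of
persons** — areal food-insecurity totals are reported on that scale, and
it keeps cell means at order 1–100, the informative Poisson regime in
which the four structures are actually distinguishable (per-person counts
would saturate every model's likelihood and make WAIC comparisons
vacuous). Per-area populations are drawn log-uniformly on 0.1–200 million
(the span of African national populations) and held constant over years.

Defaults for the `anova` variant are the published operating point for
this model family: five standardised covariates with coefficients
(-0.218, 0.085, -0.129, 0.143, 0.255), `rho_s = 0.387`, `rho_T = 0.415`,
`tau2_s = 0.657`, `tau2_T = 0.144`, `tau2_int = 0.223`. An intercept of
-2.5 on the log-rate scale (~8% prevalence) is added, and is the package's
own choice — realistic severity for the phenomenon modelled. Values for
the other variants reuse printed estimates where they exist and
conventional magnitudes otherwise (`linear`: tau2 1.143/1.438, rho
0.099/0.017, omega (-2.5, -0.05); `separable`: per-year tau2 0.3, temporal
tau2 0.713, rho 0.023/0.446; `ar`: tau2 0.5, rho 0.018/0.232).

CAR fields are drawn exactly via a Cholesky factor of the precision
(`L'x = z`), trivially cheap at n = 54, and centred to sum to zero at
generation, matching the fitting-side identifiability convention. The
default spatial graph is a deterministic trimmed rook lattice (a seeded
random geometric graph is also provided); any user edge list, GAL file or
JSON graph substitutes a real contiguity structure.

The indicator generator emits a 1080 x 40 table with 10 standard-normal
latent factors, random N(0, 1) loadings and independent noise. Its default
noise level (sd 2.13) was calibrated once so the first ten principal
components of the correlation matrix explain ~74.6% of total variance —
the share a ten-component reduction of a real 40-indicator food-security
table retains.

What the generator deliberately does not emulate: survey measurement
error and survey-to-scale calibration, missing data (panels are complete),
population growth over time, and real contiguity geometry. Passing tests
therefore certify the statistical machinery under the models' own
assumptions, not robustness to those real-data complications.

## Covariate reduction

PCA is performed on the correlation matrix (indicators mix units), via a
direct symmetric eigendecomposition; eigenvector signs are pinned so each
component's largest-magnitude loading is positive, making loadings
platform-reproducible. The component count is fixed by configuration (ten
in the reference pipeline); a Kaiser-rule helper exists but is not the
default. Rows are pooled across years before fitting (the alternative —
time-averaged rows — can be had by pre-aggregating the table).

## Assessment

WAIC uses the variance-based penalty with sample-variance denominator
S - 1, computed from the thinned pointwise log-likelihoods stored during
sampling; for hold-out fits it covers training cells only. Credible
intervals are equal-tailed percentile intervals. Hold-out validation
splits the 1080 cells at random (70/30 by default; whole-area and
whole-year splits are options), refits with the likelihood masked to
training cells — held-out cells' latent effects are then sampled from
their prior structure conditioned on neighbours, which is exactly
"redrawn from the prior" for the iid interaction block — and builds 95%
predictive intervals from Poisson draws at each retained iteration's cell
mean. For discrete counts such equal-tailed intervals are conservative:
when many cells have means below 1 (small-population areas), realised
coverage sits several points above the nominal 95% — around 98% under the
default generator, where the exact intervals at the true rates already
cover ~98.5% in expectation. Percentile maps assign `100 (rank - 1)/n` with average ranks for
ties, so exactly the top half of distinct areas sits at or above the 50th
percentile.

## Numerical and design choices

- Problem sizes in the test-suite studies are the package's choices for a
  single-core desk run: recovery fits use 30,000-iteration chains
  (5,000 burn-in, thin 5), comparison and validation studies 6,000–8,000
  iteration chains; at 1080 cells a 30,000-iteration ANOVA fit takes
  ~15 s.
- `exp(eta)` is maintained incrementally across accepted single-site
  moves and refreshed from scratch every 500 sweeps to kill float drift.
- The linear-trend variant carries its overall intercept in `omega_1`, so
  its design matrix takes no intercept column; a printed `alpha` for that
  variant is read as `omega_1` (the alternative reading — an overall
  slope — is noted but not used).
- Empty graphs, isolated areas (islands) and constant inputs are flagged:
  islands are permitted with a warning (their CAR conditional degenerates
  to N(0, tau2/(1 - rho))), Moran's I refuses constant vectors and
  edgeless graphs, and `rho = 1` density evaluation raises.
- Moran's I uses raw binary weights (no row standardisation), matching
  the precision-matrix convention; it is provided for counts, rates or
  residuals without prescribing which.

## Known limitations

- Single-site Metropolis mixes slowly for very strong spatial dependence
  (`rho > 0.99`) or enormous counts; blocked or marginal updates are out
  of scope.
- WAIC is the only comparison criterion (no DIC/LOO-CV).
- The hold-out procedure assumes missingness at random by construction;
  structured missingness is not modelled.
- Per-year variances in the `separable` variant are weakly identified on
  short panels; use the pooled option there.
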