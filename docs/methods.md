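# Methods

## Model

Counts are cross-tabulated by maternal age *j* (default 15–49, J=35)
and paternal age *k* (default 15–65, K=51). Each cell is an independent
binomial: `Y_jk ~ Binomial(n_jk, mu_jk)` with
`logit(mu_jk) = alpha + maternal_j + paternal_k`. Cells with no births
are kept in the rectangular grid and contribute exactly zero
likelihood.

Age terms come in four forms per parent:

* **car** — one effect per year of age under a first-order random-walk
  (RW1 / intrinsic CAR) prior: up to a constant,
  `log p(e | tau) = ((L-1)/2) log tau - (tau/2) * sum (e_a - e_{a-1})^2`.
  The prior is improper in the level (the structure matrix has the
  constant vector in its null space), so effect vectors are constrained
  to sum to zero and the intercept carries the level. The smoothing SD
  `sigma = 1/sqrt(tau)` has a Uniform(0, 10) hyperprior on the open
  interval — wide enough to be minimally informative on the log-odds
  scale while excluding the degenerate `tau = infinity` boundary.
* **linear** and **curvilinear** — `beta*(age-c)` and
  `beta*(age-c) + gamma*(age-c)^2` with N(0, 1000) coefficient priors.
  Covariates are centred at the midpoint of each parent's range
  (maternal 32, paternal 40) purely for conditioning; this is a
  reparameterisation that leaves fitted probabilities and DIC
  unchanged.
* **category5** — a constant per 5-year band (15–19 … 45–49, with
  50–54, 55–59 and the six-year 60–65 band added for fathers), youngest
  band as the reference level, N(0, 1000) priors.

The single-parent CAR models (presets `model1`, `model2`) use a flat
improper intercept prior, as does the joint CAR model (`model3`); the
fixed-form comparison models use N(0, 1000) intercepts. Comparison
models are fitted on the full J×K grid, not on band-collapsed counts,
so their deviances are directly comparable.

## Posterior simulation

The default protocol is 5000 burn-in iterations and 10000 retained
iterations on each of two chains, with chain starting values offset by
±2 on the logit scale.

The engine is an exact Metropolis-within-Gibbs sampler built on
Gaussian (IWLS/Laplace) approximations:

1. **Coefficient refresh.** The full coefficient vector (intercept plus
   all age terms, with CAR blocks in a sum-to-zero basis so the joint
   precision is nonsingular) is proposed from the normal approximation
   of its conditional posterior at the IWLS mode and accepted or
   rejected against the exact binomial-logit target. The proposal is a
   defensive mixture — 0.9 Gaussian, 0.1 multivariate t with 5 degrees
   of freedom at the same mode and scale — because the log-concave
   target has near-exponential tails: a pure Gaussian proposal is
   lighter-tailed than the target and an independence chain can stall
   at tail points, while the t component keeps the importance ratio
   bounded.
2. **Smoothing precisions.** Each RW1 precision `tau` gets a joint move
   that proposes `log tau` by a random walk and a fresh coefficient
   vector from the Laplace approximation at the proposed `tau`,
   accepted jointly. This sidesteps the notoriously sticky
   `tau <-> effects` conditional; the proposal SD is batch-adapted
   toward 23% acceptance during burn-in and frozen afterwards.

Updating the whole coefficient vector in one block matters: with
parental-age correlation near 0.8 the likelihood is weakly informative
about how a shared trend splits between the two curves, and
single-block Gibbs crawls along exactly that direction.

Two properties of birth-registry data make this design efficient: cell
counts are huge and events rare, so the coefficient posterior is
extremely close to Gaussian and acceptance rates sit around 0.8–0.97,
giving near-iid mixing. Pólya-Gamma data augmentation — the standard
conjugate alternative for binomial-logit models — was evaluated and
rejected: for rare events its augmented conditionals are far tighter
than the posterior (by roughly the ratio of `n/(2|psi|)` to
`n*mu*(1-mu)`, two orders of magnitude here), yielding effective sample
sizes of a few per thousand draws.

Gradient and Hessian assembly exploits the grid structure: every term
acts along one axis of the J×K table, so the information matrix is
built from axis sums of the weight grid rather than per-cell design
matrices (~40× fewer floating-point operations; about 2 ms per
iteration for the joint model).

Correctness oracles: on a single binomial cell with a flat intercept
prior, the sampled `mu` must match the analytic Beta(y, n−y) posterior
(Kolmogorov–Smirnov check); on a three-age CAR model with fixed `tau`,
sampler moments must match brute-force quadrature over the three free
parameters. Both run in the test suite. Fits are bit-reproducible given
(data, model, protocol, seed); per-chain seeds are spawned from the
protocol seed.

## Convergence and model comparison

`check_convergence` computes split-R̂ and effective sample size per
scalar parameter via ArviZ and passes when max R̂ ≤ 1.05 (a quantitative
stand-in for visual multi-chain checking). Constant parameters (pinned
references) are excluded.

DIC uses the classic plug-in at the posterior mean of the per-cell
probabilities `mu_jk` — the direct stochastic parents of the counts —
so `pD = Dbar - D(mean mu)` and `DIC = Dbar + pD`. For the fixed-form
models pD lands on the free-parameter count (≈3 linear, ≈5
curvilinear), a built-in sanity check.

## Summaries

Odds ratios are computed per draw and summarised by 2.5/50/97.5
percentiles — percentiles of transformed draws, never transforms of
percentiles; intervals are equal-tailed, not HPD. Two baselines: a
reference age (default 15, exactly OR 1 with zero-width interval), and
the overall mean risk, defined as the births-weighted mean of the cell
linear predictors (an unweighted variant is available; the weighted
version makes the baseline the population-average log-odds). Exceedance
probabilities use the strict inequality OR > 1, so ties count as
non-exceedance and the reference age has exceedance 0.

## Synthetic cohorts

The generator emulates the structure of national natality cross-tabs:

* age pairs from a discretised bivariate normal — maternal mean 29 y
  (SD 6), paternal mean 32 y (SD 7), correlation 0.8 — chosen to mimic
  the qualitative joint age structure of US births and to produce
  realistic confounding strength; births are a single multinomial draw,
  so the total is conserved exactly;
* a rare outcome: baseline prevalence 5.4 per 10,000 births, the scale
  of Down syndrome in the eligible cross-tab (`base_rate` is the
  prevalence where the raw truth curve is zero; the population
  prevalence is higher when a risk ramp is present);
* truth curves on the log-odds scale: flat, linear, or a smoothstep
  ramp with inflection ages (default 30 and 45, the shape reported for
  the maternal trisomy-risk curve). Truth curves are returned centred
  to sum to zero for direct comparison with CAR estimates.

What it does **not** emulate: calendar-time trends, clustering within
mothers (plural births, repeat births), reporting error in ages or
diagnoses, and prenatal-diagnosis/termination selection. Passing
recovery tests therefore demonstrates statistical correctness of the
estimator under the stated sampling model, not robustness to those
real-data features.

## Problem sizes and numerical choices

* Test and validation fits use reduced protocols (300/600 iterations,
  1–2 chains) on cohorts of 10^6–2×10^6 births; the near-iid mixing of
  the sampler makes these ample for interval-based checks, and the
  50-replicate recovery study completes in under two minutes. The
  acceptance script uses 1000/2000 × 2 chains on a 10^7-birth cohort.
* Newton iterations stop at Newton decrement < 1e-8 with step halving
  as a safeguard; the Cholesky factor at the mode doubles as proposal
  scale.
* A zero-case table leaves the flat-prior intercept unidentified; the
  fit warns and caps mode-search iterations rather than failing.
* The OpenBUGS rectangular reader fills `structure(.Data=...)` blocks
  row-major over (j, k) — the BUGS convention, not R's column-major
  fill — and assumes age grids start at 15, matching the published
  tables' layout.
* Missing CSV cells inside the declared age rectangle are an error
  unless `allow_sparse=True`; silent zero-filling hides mangled data.

## Known limitations

* The marginal models (`model1`, `model2`) are fitted to marginal
  tables; they are the classic *unadjusted* analyses, not
  restrictions of the joint model.
* DIC is the only fit criterion implemented (no WAIC/LOO), matching
  the comparison it was built to reproduce.
* The RW1 prior smooths adjacent ages only; RW2, splines, or proper
  CAR variants with wider neighbourhoods are out of scope.
* Absolute-risk (prevalence-scale) prediction per age pair and
  attributable-fraction summaries are not provided.
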