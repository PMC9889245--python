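# Methods

## Model

`stcar` fits a Bayesian space-time Poisson lognormal model for an
area-by-year panel of event counts `y_it` (areas `i = 1..N`, years
`t = 1..T`) with area-level covariates `X_it`:

    y_it ~ Poisson(mu_it)
    log mu_it = alpha + X_it beta + phi_i + xi_t + delta_it

* `alpha` — overall log level; `exp(alpha)` is the expected yearly count in
  an average area (covariates are centred), flat prior.
* `beta` — covariate effects, Normal(0, 1000) priors.
* `phi` — spatially structured residuals with an intrinsic CAR (ICAR)
  prior on the contiguity graph: `phi_i | phi_-i ~ N(mean of neighbours,
  var_phi / n_i)`, where `n_i` is the neighbour count.
* `xi` — national temporal trend, first-order random walk:
  `xi_t | xi_{t-1} ~ N(xi_{t-1}, var_xi)`.
* `delta` — space-time interaction: an independent RW1 per area with
  innovation variance `var_delta`, letting each area's trend deviate
  smoothly from the national one while remaining independent across space.
* The three precisions `1/var_*` have Gamma(0.5, 0.005) priors (prior mean
  precision 100).

### Identifiability

The ICAR and RW1 priors are improper (invariant to level shifts).  We fix

* `sum_i phi_i = 0` over non-isolated areas,
* `sum_t xi_t = 0`,
* `sum_t delta_it = 0` for every area `i`,

by recentring after every MCMC sweep.  The removed `phi` and `xi` levels
are absorbed into the flat-prior intercept, and the removed `delta` row
means into `phi`, so the linear predictor — hence the posterior — is
unchanged and recentring is a valid deterministic move.  On a graph with
several connected components only the single global `phi` constraint is
imposed: the likelihood itself separates component levels from the
intercept, leaving exactly one flat direction, and per-component recentring
could not be absorbed by a single scalar intercept without changing the
likelihood.  (On connected graphs — every lattice fixture here, and any
national contiguity map after island removal — global and per-component
constraints coincide.)  Column means of `delta` remain confounded with
`xi`; the prior's shrinkage resolves this softly and the model does not
doubly-constrain, a documented caveat.

Isolated areas have no CAR conditional (`n_i = 0`); they receive an
exchangeable Normal(0, var_phi) prior sharing the spatial variance, are not
recentred, and contribute an iid-style term to the variance update.

### Sampler

Metropolis-within-Gibbs, one sweep per iteration:

1. **alpha** — exact conjugate draw: with a flat prior,
   `exp(alpha) | rest ~ Gamma(sum y, sum exp(eta - alpha))`.  This replaces
   a random-walk update; it is exact, rejection-free, and removes the
   slowest mixing direction.  (A random-walk fallback covers the
   all-zero-count corner case.)
2. **beta** — single-site adaptive random-walk Metropolis per coordinate
   (target acceptance 0.44, Robbins–Monro adaptation confined to burn-in;
   in prior-only mode the initial step is 2.4 × prior sd).
3. **phi, xi, delta** — single-site random-walk Metropolis vectorised over
   colour classes: a greedy colouring of the contiguity graph for `phi`,
   even/odd time parity for `xi` and for the columns of `delta`.  Sites
   within a class are conditionally independent given the rest, so
   simultaneous accept/reject decisions leave the target invariant while
   the whole class is updated with a handful of numpy operations.
4. Recentring (above), then conjugate Gibbs draws of the precisions:
   `1/var_phi ~ Gamma(a + rank/2, b + phi'(D-W)phi/2)` with
   `rank = N - #components` (isolated areas add iid terms),
   `1/var_xi ~ Gamma(a + (T-1)/2, b + sum diff(xi)^2/2)`,
   `1/var_delta ~ Gamma(a + N(T-1)/2, b + sum row-increments^2/2)`.

The linear predictor and its exponential are maintained incrementally
(each accepted site update touches one row, column or cell) and refreshed
from scratch every 500 iterations to kill rounding drift.  Proposals that
would push any `log mu` above 30 are rejected outright — a hard guard
against overflow that binds only in pathological states.  Chains start
over-dispersed: `alpha` at the log mean count, fields jittered with a
chain-dependent scale.  Persistent acceptance rates outside (1%, 99%)
raise a tuning warning.

Correctness is verified three independent ways: exact closed-form
full conditionals on tiny graphs; a dense-grid numerical-integration
oracle on a constraint-reduced 2-area × 2-year model (posterior means of
`alpha`, `beta` agree within 3 Monte-Carlo standard errors); and the
no-random-effects limit, where the posterior matches the maximum-likelihood
Poisson regression (statsmodels) within its standard error.

## Synthetic data generator

`stcar.synthetic` draws panels from exactly the model above with known
ground truth, under the same sum-to-zero conventions as the sampler (so
recovery tests are unbiased): ICAR fields via the spectral pseudo-inverse
of the graph Laplacian per connected component, RW1 paths started at 0 and
recentred, independent per-area RW1 interactions, Poisson emission.

The reference configuration emulates a decade-long English
local-authority panel: a 10×10 rook lattice (100 areas) standing in for
the contiguity map, T = 10 years, P = 6 pre-centred standard-normal
covariates with coefficients (0.11, 0.03, −0.55, 0.69, −0.01, 0.08),
`exp(alpha) = 11.22`, and variances `var_phi = 0.535`, `var_xi = 0.022`,
`var_delta = 0.004` — the magnitudes estimated from such data.  What it
deliberately does **not** emulate: the real covariates' marginal
distributions, their mutual correlation and spatial structure, boundary
changes over time, or the irregular degree distribution of a real
contiguity map.  Passing recovery tests therefore demonstrate that the
inference machinery is correct under the assumed generative structure, not
that the model is adequate for any particular real dataset — that is what
the WAIC comparison and posterior predictive checks are for.

## Diagnostics

* **Gelman–Rubin** — split-chain PSRF,
  `sqrt((n-1)/n + (m+1)/(m n) B/W)`; splitting each chain in half is more
  conservative than the original two-chain form and also detects
  within-chain drift.  Returns not-available (NaN, with a warning) when
  every chain has zero within-chain variance.
* **WAIC** — deviance scale, `-2 (lppd - p_waic)`, pointwise over the
  N·T cells, `lppd` via stabilised log-sum-exp, `p_waic` the sample
  (ddof = 1) posterior variance of the pointwise log-likelihood;
  cross-checked against ArviZ in the tests.
* **Bayesian p-values** — default is the per-cell discrete mid-p tail
  probability `P(y_rep > y) + 0.5 P(y_rep = y)` under the posterior
  predictive, computed in closed form by averaging Poisson tails over
  draws, then averaged over cells (0.5 = perfectly calibrated; the ±half
  point-mass term is the standard continuity correction that keeps the
  value in [0, 1] and centred for discrete outcomes).  A global chi-square
  discrepancy variant (`sum (y - mu)^2 / mu`, estimated with one replicate
  panel per draw) is exposed as an alternative; neither is claimed to be
  uniquely canonical.

## Posterior products

* **Marginal effects** — per draw,
  `ME_p = (1/(N T)) sum_it mu_it * beta_p`: the absolute change in expected
  yearly counts per unit covariate change at the average fitted mean.  The
  average runs over all N·T cells (the panel's observations); coefficients
  are not area-specific.
* **Hotspots** — `P(exp(phi_i) > 1)` (= `P(phi_i > 0)`), flagged above
  0.9.  Invariant to any strictly increasing transform of `exp(phi)`.
* **Expected-count gaps** — per year, `max_i mu_it - min_i mu_it` computed
  per draw then summarised, a genuine posterior of the gap.
* **Trend exceedance** — area trend = `xi_t + delta_it`; exceedance of the
  national trend is `P(delta_it > 0)` per cell, exact-zero draws counted
  as 1/2 (so the no-interaction limit reports 0.5 everywhere).  An
  alternative based on full incidence ratios would fold covariate and
  spatial differences into the comparison; the delta-based reading isolates
  the *temporal* deviation and is the default.
* **Deprivation gradient** — per draw and year, the OLS slope of
  `log mu_it` on the (uncentred) deprivation covariate across areas, plus
  the posterior of the between-year slope difference.

## Problem sizes and numerical choices

Default MCMC settings are 4 chains × (20,000 burn-in + 5,000 retained) =
20,000 post burn-in draws.  The test suite and the acceptance script use
the 10×10 lattice fixture with shorter chains chosen by convergence
diagnostics — e.g. 2 chains × (5,000 + 2,000) gives split-Rhat < 1.02 for
all scalar parameters there; replicate studies (coverage over 50
simulated panels, WAIC selection over 20 seeds × 2 generative conditions)
use single chains of 600–1,500 retained draws, which the grid-oracle and
GLM-limit tests show are unbiased.  Variance draws are floored at 1e-12.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds give bit-identical chains.

## Known limitations

* The space-time interaction is the independent-RW1-per-area form only; no
  spatially structured (Knorr-Held type III/IV) interactions.
* No INLA-style deterministic approximation; MCMC only.
* Polygon input for contiguity is GeoJSON; areas touching at a single
  point are not neighbours (rook rule).
* WAIC is the only model-comparison criterion (no LOO), and convergence
  checking offers the split-PSRF only (no ESS-based stopping).
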