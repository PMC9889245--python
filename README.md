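# stcar — Bayesian space-time CAR models for areal count panels

`stcar` is for epidemiologists and safety analysts who work with small-area
event counts observed over several years — road crashes, injuries, disease
cases aggregated to administrative districts — and who want to separate
covariate effects, persistent spatial risk patterns, the national time
trend, and area-specific departures from that trend, with full posterior
uncertainty.

## Model

Counts `y_it` in area `i` and year `t` follow a Poisson lognormal model

```
y_it ~ Poisson(mu_it)
log mu_it = alpha + X_it beta + phi_i + xi_t + delta_it
```

with an intrinsic CAR (ICAR) prior on the spatial residuals
`phi_i | phi_-i ~ N(mean of neighbours, sigma2_phi / n_i)` over the
shared-border contiguity graph, a first-order random walk
`xi_t | xi_{t-1} ~ N(xi_{t-1}, sigma2_xi)` for the national trend, and an
independent RW1 per area for the space-time interaction
`delta_it | delta_{i,t-1} ~ N(delta_{i,t-1}, sigma2_delta)`.  Priors:
flat on `alpha`, Normal(0, 1000) on `beta`, Gamma(0.5, 0.005) on the
inverse variances.  Inference is Metropolis-within-Gibbs MCMC (exact
conjugate updates for the intercept and the variances, adaptive
colour-blocked Metropolis for the latent fields); see `docs/methods.md`
for the full account.

From the posterior draws the package computes marginal covariate effects
`(1/NT) sum_it mu_it * beta_p`, expected counts and between-area gaps,
hotspot exceedance probabilities `P(exp(phi_i) > 1)` with flagging at 0.9,
area-specific trends `xi_t + delta_it` and their probability of exceeding
the national trend, deprivation gradients, WAIC model comparison,
split-chain Gelman-Rubin convergence checks and posterior predictive
Bayesian p-values.

## Worked example

Simulate a panel with known truth on a 10×10 lattice (100 areas, 10
years, six centred covariates, `exp(alpha) = 11.22`, variances 0.535 /
0.022 / 0.004), fit the full model, and summarise:

```python
import numpy as np
from stcar import (make_lattice_graph, paper_like_truth, simulate_panel,
                   ModelConfig, run_mcmc, diagnose, summarise)

graph = make_lattice_graph(10, 10)                  # 100 areas, rook contiguity
truth = paper_like_truth(graph, T=10, seed=11)      # known ground truth
panel, truth = simulate_panel(graph, truth, seed=12)

cfg = ModelConfig(n_chains=2, n_burnin=5000, n_samples=4000, seed=13)
post = run_mcmc(panel, graph, cfg)

diag = diagnose(post, panel)
print(f"WAIC {diag.waic:.1f}   avg Bayesian p {diag.bayes_p_mean:.3f}   "
      f"max split-Rhat {diag.rhat.max():.3f}")

summary = summarise(post, panel)
print(summary.marginal_effects.round(3).to_string(index=False))
print(f"hotspots flagged: {int(summary.hotspots['hotspot'].sum())}/100")
print(f"exp(alpha): {np.exp(post.stacked('alpha')).mean():.2f}  (truth 11.22)")
```

prints

```
WAIC 5434.5   avg Bayesian p 0.500   max split-Rhat 1.015
covariate    mean    sd    q2.5  median   q97.5
       x1   2.163 0.164   1.844   2.162   2.488
       x2   0.656 0.156   0.361   0.651   0.962
       x3 -10.645 0.203 -11.047 -10.645 -10.233
       x4  13.370 0.189  12.993  13.369  13.745
       x5  -0.208 0.168  -0.552  -0.206   0.118
       x6   1.801 0.159   1.478   1.804   2.109
hotspots flagged: 36/100
exp(alpha): 11.35  (truth 11.22)
```

The average Bayesian p-value of 0.500 says the model replicates its own
data perfectly (as it should here); all split-Rhat below 1.05 indicate the
two chains agree; the marginal-effects table gives, per covariate, the
posterior of the change in expected yearly counts per unit covariate
change (e.g. one unit of `x4`, injected at coefficient 0.69, adds about
13.4 expected events per area-year); 36 of 100 areas have
`P(exp(phi_i) > 1) > 0.9` and are flagged as hotspots; and the intercept
recovers the injected overall level.

The same pipeline runs from the shell on any CSV panel + neighbour-pair
list (or GeoJSON polygons via `stcar.adjacency_from_polygons`):

```
stcar simulate --rows 10 --cols 10 --years 10 --seed 1 --out panel.csv
stcar fit --panel panel.csv --adjacency adjacency.csv --chains 4 --out samples.npz
stcar diagnose --samples samples.npz --panel panel.csv --out diag/
stcar summarise --samples samples.npz --panel panel.csv --out summary/
```

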