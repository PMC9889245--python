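import numpy as np
import pytest
from hypothesis import settings

from stcar import ModelConfig, make_lattice_graph, paper_like_truth, run_mcmc, simulate_panel
from stcar.model import PosteriorSamples

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice10():
    return make_lattice_graph(10, 10)


@pytest.fixture(scope="session")
def paper_panel(lattice10):
    """The reference fixture: 10x10 lattice, T=10, variances near the
    motivating analysis's posterior means, six covariates."""
    truth = paper_like_truth(lattice10, T=10, seed=11)
    panel, truth = simulate_panel(lattice10, truth, seed=12)
    return panel, truth


@pytest.fixture(scope="session")
def fitted_paper(lattice10, paper_panel):
    """Full model fitted to its own simulated data, two chains."""
    panel, _ = paper_panel
    cfg = ModelConfig(n_chains=2, n_burnin=5000, n_samples=4000, seed=13)
    return run_mcmc(panel, lattice10, cfg)


def manual_samples(
    alpha,
    beta=None,
    phi=None,
    xi=None,
    delta=None,
    area_ids=None,
    years=None,
    covariate_names=None,
    **config_kw,
):
    """Hand-built PosteriorSamples (one chain) for closed-form checks.

    All arrays are (draws, ...); missing components default to zeros
    inferred from the others.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    s = alpha.shape[0]
    if beta is None:
        beta = np.zeros((s, 0))
    beta = np.asarray(beta, dtype=float).reshape(s, -1)
    if phi is None:
        n = np.asarray(delta).shape[-2] if delta is not None else 1
        phi = np.zeros((s, n))
    phi = np.asarray(phi, dtype=float).reshape(s, -1)
    n = phi.shape[1]
    if xi is None:
        t = np.asarray(delta).shape[-1] if delta is not None else 1
        xi = np.zeros((s, t))
    xi = np.asarray(xi, dtype=float).reshape(s, -1)
    t = xi.shape[1]
    if delta is None:
        delta = np.zeros((s, n, t))
    delta = np.asarray(delta, dtype=float).reshape(s, n, t)
    cfg = ModelConfig(n_chains=1, n_burnin=1, n_samples=s, **config_kw)
    return PosteriorSamples(
        alpha=alpha[None],
        beta=beta[None],
        phi=phi[None],
        xi=xi[None],
        delta=delta[None],
        var_phi=np.ones((1, s)),
        var_xi=np.ones((1, s)),
        var_delta=np.ones((1, s)),
        acceptance=[{}],
        config=cfg,
        area_ids=area_ids or [f"a{i}" for i in range(n)],
        years=np.asarray(years) if years is not None else np.arange(2011, 2011 + t),
        covariate_names=list(covariate_names or []),
    )
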