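"""Metropolis-within-Gibbs MCMC for the space-time Poisson lognormal model.

Model
-----
    y_it ~ Poisson(mu_it)
    log mu_it = alpha + X_it beta + phi_i + xi_t + delta_it

with priors

    phi  : intrinsic CAR,  phi_i | phi_-i ~ N(mean of neighbours, var_phi/n_i)
    xi   : RW1,            xi_t | xi_{t-1} ~ N(xi_{t-1}, var_xi)
    delta: independent RW1 per area, delta_it ~ N(delta_{i,t-1}, var_delta)
    alpha ~ flat,  beta_p ~ N(0, 1000),  1/var_* ~ Gamma(0.5, 0.005)

The ICAR and RW1 priors are improper; identifiability is restored by
sum-to-zero constraints (phi over non-isolated areas, xi over t, each row
of delta over t) re-imposed by recentring after every sweep, with the
compensating level shifts absorbed into the flat-prior intercept (phi, xi)
or into phi (row means of delta).  Recentring leaves the linear predictor,
hence the posterior, untouched, so it is a valid deterministic move.

Sampler
-------
alpha has an exact conjugate update: with a flat prior on alpha,
exp(alpha) | rest ~ Gamma(sum y, sum exp(eta - alpha)).  beta uses adaptive
single-site random-walk Metropolis.  phi, xi and delta use single-site
random-walk Metropolis vectorised over conditionally independent colour
classes of the (spatial or temporal) dependence graph: sites of one colour
have no edges among themselves, so simultaneous accept/reject decisions
leave the target invariant.  Variances are conjugate Gibbs draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .panel_io import AdjacencyGraph, AreaPanel

logger = logging.getLogger(__name__)

_ETA_MAX = 30.0  # proposals pushing any log-mean beyond this are rejected
_VAR_FLOOR = 1e-12


@dataclass
class ModelConfig:
    """Priors, structural flags and MCMC settings.

    ``n_samples`` is the total number of retained draws across all chains
    (the per-chain count is ``ceil(n_samples / n_chains)``); the default
    4 x 5000 = 20,000 post burn-in draws matches common practice for this
    model class.  ``fixed_variances`` pins any of var_phi / var_xi /
    var_delta instead of sampling them (used by oracle tests).
    """

    prior_precision_shape: float = 0.5
    prior_precision_rate: float = 0.005
    beta_prior_variance: float = 1000.0
    n_chains: int = 4
    n_burnin: int = 20000
    n_samples: int = 20000
    thin: int = 1
    seed: int = 0
    include_spatial: bool = True
    include_temporal: bool = True
    include_interaction: bool = True
    spatial_structure: Literal["icar", "iid"] = "icar"
    fixed_variances: dict | None = None
    proposal_scales: dict | None = None
    store_delta: bool = True
    prior_only: bool = False

    def __post_init__(self) -> None:
        if self.prior_precision_shape <= 0 or self.prior_precision_rate <= 0:
            raise ValueError("prior precision shape and rate must be positive")
        if self.beta_prior_variance <= 0:
            raise ValueError("beta_prior_variance must be positive")
        if self.n_samples < 1 or self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_samples, n_chains and thin must be >= 1")
        if self.spatial_structure not in ("icar", "iid"):
            raise ValueError("spatial_structure must be 'icar' or 'iid'")

    @property
    def samples_per_chain(self) -> int:
        return -(-self.n_samples // self.n_chains)

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


#: competing specifications for WAIC comparison: the full model and the
#: four reduced/alternative structures
MODEL_VARIANTS: dict[str, dict] = {
    "full": {},
    "no_interaction": {"include_interaction": False},
    "iid_spatial": {"spatial_structure": "iid"},
    "no_spatial": {"include_spatial": False},
    "no_temporal": {"include_temporal": False},
}


def log_mean(alpha, beta, X_it, phi_i=0.0, xi_t=0.0, delta_it=0.0) -> float:
    """Linear predictor for one cell: alpha + X_it . beta + phi_i + xi_t + delta_it."""
    out = float(alpha + np.dot(np.atleast_1d(X_it), np.atleast_1d(beta)) + phi_i + xi_t + delta_it)
    if not np.isfinite(out):
        raise FloatingPointError("non-finite log-mean")
    return out


def car_full_conditional_params(
    i: int, phi: np.ndarray, graph: AdjacencyGraph, var_phi: float
) -> tuple[float, float]:
    """Prior full conditional of phi_i under the intrinsic CAR.

    Returns (neighbour mean, var_phi / n_i).  An isolated area (n_i = 0)
    has no CAR conditional; it is given the exchangeable Normal(0, var_phi)
    prior instead.
    """
    nb = graph.neighbours[i]
    if not nb:
        return 0.0, float(var_phi)
    nb = sorted(nb)
    return float(np.mean(phi[nb])), float(var_phi / len(nb))


def variance_posterior_params(
    kind: Literal["phi", "xi", "delta"],
    values: np.ndarray,
    graph: AdjacencyGraph | None = None,
    *,
    shape: float = 0.5,
    rate: float = 0.005,
    spatial_structure: str = "icar",
) -> tuple[float, float]:
    """Gamma posterior (shape, rate) of the precision of one random-effect block.

    phi/icar : shape + rank/2 with rank = N - #components (+ one half per
               isolated area, whose exchangeable normal prior contributes
               like an iid term), rate + (phi' (D-W) phi + sum_iso phi^2)/2.
    phi/iid  : shape + N/2, rate + sum phi^2 / 2.
    xi       : shape + (T-1)/2, rate + sum (xi_t - xi_{t-1})^2 / 2.
    delta    : shape + N(T-1)/2, rate + sum of squared row increments / 2.
    """
    values = np.asarray(values, dtype=float)
    if kind == "phi":
        if spatial_structure == "iid":
            return shape + values.size / 2.0, rate + float(values @ values) / 2.0
        if graph is None:
            raise ValueError("icar variance update needs the adjacency graph")
        quad = 0.0
        for i, j in graph.edges:
            quad += (values[i] - values[j]) ** 2
        iso = np.flatnonzero(graph.n == 0)
        quad += float(values[iso] @ values[iso])
        dof = graph.n_areas - len(graph.components) + len(iso)
        return shape + dof / 2.0, rate + quad / 2.0
    if kind == "xi":
        d = np.diff(values)
        return shape + (values.size - 1) / 2.0, rate + float(d @ d) / 2.0
    if kind == "delta":
        d = np.diff(values, axis=1)
        n, tm1 = d.shape
        return shape + n * tm1 / 2.0, rate + float((d * d).sum()) / 2.0
    raise ValueError(f"unknown kind {kind!r}")


def update_variances(
    state: Mapping[str, np.ndarray],
    graph: AdjacencyGraph,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Conjugate Gibbs draws of (var_phi, var_xi, var_delta) given the fields."""
    a, b = config.prior_precision_shape, config.prior_precision_rate
    out = []
    for kind, key in (("phi", "phi"), ("xi", "xi"), ("delta", "delta")):
        sh, ra = variance_posterior_params(
            kind, state[key], graph, shape=a, rate=b,
            spatial_structure=config.spatial_structure,
        )
        prec = max(rng.gamma(sh, 1.0 / ra), _VAR_FLOOR)
        out.append(1.0 / prec)
    return tuple(out)


def _colour_classes(g: nx.Graph) -> list[np.ndarray]:
    colouring = nx.greedy_color(g, strategy="largest_first")
    ncol = 1 + max(colouring.values(), default=0)
    return [
        np.array(sorted(i for i, c in colouring.items() if c == k), dtype=int)
        for k in range(ncol)
    ]


class _Sampler:
    """One-chain sampler state and update kernels."""

    def __init__(
        self,
        panel: AreaPanel,
        graph: AdjacencyGraph,
        config: ModelConfig,
        rng: np.random.Generator,
    ):
        if list(graph.area_ids) != list(panel.area_ids):
            raise ValueError("graph and panel area_ids differ (order matters)")
        self.cfg = config
        self.rng = rng
        self.y = panel.counts.astype(float)
        self.X = panel.covariates
        self.N, self.T, self.P = self.X.shape
        if self.T < 2 and (config.include_temporal or config.include_interaction):
            raise ValueError("temporal structure needs T >= 2")
        self.graph = graph
        self.ysum_rows = self.y.sum(axis=1)
        self.ysum_cols = self.y.sum(axis=0)
        self.S_y = float(self.y.sum())
        self.yX = np.einsum("nt,ntp->p", self.y, self.X)

        n = graph.n_areas
        rows, cols = [], []
        for i, j in graph.edges:
            rows += [i, j]
            cols += [j, i]
        self.W = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        self.n_nb = graph.n.astype(float)
        self.isolated = graph.n == 0
        self.noniso = np.flatnonzero(~self.isolated)
        self.phi_classes = _colour_classes(graph.to_networkx())
        tc = np.arange(self.T)
        self.t_classes = [tc[tc % 2 == 0], tc[tc % 2 == 1]]
        self.t_nbr_count = ((tc > 0).astype(float) + (tc < self.T - 1)).astype(float)

        # adaptive proposal scales (log random-walk step sizes)
        base = {"beta": 0.1, "phi": 0.3, "xi": 0.1, "delta": 0.3, "alpha": 0.3}
        if config.prior_only:
            # random-walk on the prior alone: start at the optimal ~2.4 sigma
            base["beta"] = 2.4 * float(np.sqrt(config.beta_prior_variance))
        if config.proposal_scales:
            base.update(config.proposal_scales)
        self.scales = {
            "beta": np.full(self.P, float(base["beta"])),
            "phi": float(base["phi"]),
            "xi": float(base["xi"]),
            "delta": float(base["delta"]),
            "alpha": float(base["alpha"]),
            "scale_phi": 0.3,
            "scale_xi": 0.3,
            "scale_delta": 0.3,
        }
        self._batch: dict[str, list[float]] = {}
        self._adapt_round = 0
        self.accept_counts: dict[str, float] = {}
        self.propose_counts: dict[str, float] = {}

    # -- state ----------------------------------------------------------
    def init_state(self, jitter: float = 0.1) -> None:
        cfg, rng = self.cfg, self.rng
        self.alpha = 0.0 if cfg.prior_only else float(np.log(self.y.mean() + 1e-8))
        self.beta = np.zeros(self.P)
        if not cfg.prior_only:
            self.beta += jitter * 0.1 * rng.standard_normal(self.P)
        self.phi = np.zeros(self.N)
        self.xi = np.zeros(self.T)
        self.delta = np.zeros((self.N, self.T))
        if not cfg.prior_only:
            if cfg.include_spatial:
                self.phi = jitter * rng.standard_normal(self.N)
            if cfg.include_temporal:
                self.xi = jitter * rng.standard_normal(self.T)
            if cfg.include_interaction:
                self.delta = jitter * 0.3 * rng.standard_normal((self.N, self.T))
        fixed = cfg.fixed_variances or {}
        self.var_phi = float(fixed.get("var_phi", 0.1))
        self.var_xi = float(fixed.get("var_xi", 0.01))
        self.var_delta = float(fixed.get("var_delta", 0.01))
        self._recentre()
        self._refresh_eta()
        if not np.all(np.isfinite(self.eta)):
            raise FloatingPointError(
                "non-finite log-posterior at initial state: "
                f"alpha={self.alpha}, |beta|max={np.abs(self.beta).max()}"
            )

    def load_state(self, state: Mapping) -> None:
        self.alpha = float(state["alpha"])
        self.beta = np.array(state["beta"], dtype=float)
        self.phi = np.array(state["phi"], dtype=float)
        self.xi = np.array(state["xi"], dtype=float)
        self.delta = np.array(state["delta"], dtype=float)
        self.var_phi = float(state.get("var_phi", 1.0))
        self.var_xi = float(state.get("var_xi", 1.0))
        self.var_delta = float(state.get("var_delta", 1.0))
        self._refresh_eta()

    def dump_state(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta.copy(),
            "phi": self.phi.copy(),
            "xi": self.xi.copy(),
            "delta": self.delta.copy(),
            "var_phi": self.var_phi,
            "var_xi": self.var_xi,
            "var_delta": self.var_delta,
        }

    def _refresh_eta(self) -> None:
        self.eta = (
            self.alpha
            + self.X @ self.beta
            + self.phi[:, None]
            + self.xi[None, :]
            + self.delta
        )
        self.mu = np.exp(self.eta)
        self.mu_sum = float(self.mu.sum())

    # -- bookkeeping ----------------------------------------------------
    def _track(self, block: str, accepted: float, proposed: float, adapting: bool) -> None:
        self.accept_counts[block] = self.accept_counts.get(block, 0.0) + accepted
        self.propose_counts[block] = self.propose_counts.get(block, 0.0) + proposed
        if adapting and proposed > 0:
            self._batch.setdefault(block, [0.0, 0.0])
            self._batch[block][0] += accepted
            self._batch[block][1] += proposed

    def _adapt(self) -> None:
        self._adapt_round += 1
        step = min(0.25, 2.0 / np.sqrt(self._adapt_round))
        for block, (acc, prop) in self._batch.items():
            if prop == 0:
                continue
            rate = acc / prop
            target = 0.44
            if block.startswith("beta"):
                p = int(block.split(":")[1])
                self.scales["beta"][p] *= np.exp(step * (rate - target))
            elif block in self.scales:
                self.scales[block] *= np.exp(step * (rate - target))
        self._batch = {}

    def acceptance_rates(self) -> dict[str, float]:
        return {
            b: self.accept_counts[b] / max(self.propose_counts[b], 1.0)
            for b in sorted(self.propose_counts)
        }

    # -- update kernels --------------------------------------------------
    def update_alpha(self, adapting: bool) -> None:
        if self.cfg.prior_only:
            return
        if self.S_y > 0:
            s0 = self.mu_sum * np.exp(-self.alpha)
            g = self.rng.gamma(self.S_y, 1.0 / s0)
            d = np.log(g) - self.alpha
        else:  # no events at all: random-walk fallback on the flat-prior scale
            d = self.scales["alpha"] * self.rng.standard_normal()
            dll = -self.mu_sum * np.expm1(d)
            if np.log(self.rng.random()) >= dll:
                self._track("alpha", 0, 1, adapting)
                return
        self.alpha += d
        self.eta += d
        self.mu *= np.exp(d)
        self.mu_sum = float(self.mu.sum())
        self._track("alpha", 1, 1, adapting)

    def update_beta(self, adapting: bool) -> None:
        v0 = self.cfg.beta_prior_variance
        for p in range(self.P):
            db = self.scales["beta"][p] * self.rng.standard_normal()
            new = self.beta[p] + db
            dlp = -(new**2 - self.beta[p] ** 2) / (2.0 * v0)
            if self.cfg.prior_only:
                dll = 0.0
            else:
                eta_new = self.eta + self.X[:, :, p] * db
                if eta_new.max() > _ETA_MAX:
                    self._track(f"beta:{p}", 0, 1, adapting)
                    continue
                mu_new = np.exp(eta_new)
                dll = db * self.yX[p] - (mu_new.sum() - self.mu_sum)
            if np.log(self.rng.random()) < dll + dlp:
                self.beta[p] = new
                if not self.cfg.prior_only:
                    self.eta = eta_new
                    self.mu = mu_new
                    self.mu_sum = float(mu_new.sum())
                self._track(f"beta:{p}", 1, 1, adapting)
            else:
                self._track(f"beta:{p}", 0, 1, adapting)

    def update_phi(self, adapting: bool) -> None:
        iid = self.cfg.spatial_structure == "iid"
        for idx in self.phi_classes:
            k = len(idx)
            d = self.scales["phi"] * self.rng.standard_normal(k)
            cur = self.phi[idx]
            new = cur + d
            if iid:
                dlp = -(new**2 - cur**2) / (2.0 * self.var_phi)
            else:
                nbr_sum = self.W[idx] @ self.phi
                a = self.n_nb[idx]
                a_eff = np.where(a > 0, a, 1.0)
                m = np.where(a > 0, nbr_sum / np.maximum(a, 1.0), 0.0)
                dlp = -(a_eff / (2.0 * self.var_phi)) * ((new - m) ** 2 - (cur - m) ** 2)
            srow = self.mu[idx].sum(axis=1)
            dll = d * self.ysum_rows[idx] - srow * np.expm1(d)
            ok = self.eta[idx].max(axis=1) + d <= _ETA_MAX
            acc = ok & (np.log(self.rng.random(k)) < dll + dlp)
            if acc.any():
                rows = idx[acc]
                self.phi[rows] += d[acc]
                self.eta[rows] += d[acc][:, None]
                self.mu[rows] *= np.exp(d[acc])[:, None]
            self._track("phi", int(acc.sum()), k, adapting)
        self.mu_sum = float(self.mu.sum())

    def update_xi(self, adapting: bool) -> None:
        for tc in self.t_classes:
            k = len(tc)
            if k == 0:
                continue
            d = self.scales["xi"] * self.rng.standard_normal(k)
            cur = self.xi[tc]
            new = cur + d
            a = self.t_nbr_count[tc]
            nbr = np.where(tc > 0, self.xi[tc - 1], 0.0) + np.where(
                tc < self.T - 1, self.xi[np.minimum(tc + 1, self.T - 1)], 0.0
            )
            m = nbr / a
            dlp = -(a / (2.0 * self.var_xi)) * ((new - m) ** 2 - (cur - m) ** 2)
            scol = self.mu[:, tc].sum(axis=0)
            dll = d * self.ysum_cols[tc] - scol * np.expm1(d)
            ok = self.eta[:, tc].max(axis=0) + d <= _ETA_MAX
            acc = ok & (np.log(self.rng.random(k)) < dll + dlp)
            if acc.any():
                cols = tc[acc]
                self.xi[cols] += d[acc]
                self.eta[:, cols] += d[acc][None, :]
                self.mu[:, cols] *= np.exp(d[acc])[None, :]
            self._track("xi", int(acc.sum()), k, adapting)
        self.mu_sum = float(self.mu.sum())

    def update_delta(self, adapting: bool) -> None:
        for tc in self.t_classes:
            k = len(tc)
            if k == 0:
                continue
            d = self.scales["delta"] * self.rng.standard_normal((self.N, k))
            cur = self.delta[:, tc]
            new = cur + d
            a = self.t_nbr_count[tc][None, :]
            nbr = np.where(
                (tc > 0)[None, :], self.delta[:, tc - 1], 0.0
            ) + np.where(
                (tc < self.T - 1)[None, :],
                self.delta[:, np.minimum(tc + 1, self.T - 1)],
                0.0,
            )
            m = nbr / a
            dlp = -(a / (2.0 * self.var_delta)) * ((new - m) ** 2 - (cur - m) ** 2)
            mu_c = self.mu[:, tc]
            dll = d * self.y[:, tc] - mu_c * np.expm1(d)
            ok = self.eta[:, tc] + d <= _ETA_MAX
            acc = ok & (np.log(self.rng.random((self.N, k))) < dll + dlp)
            if acc.any():
                sub = self.delta[:, tc]
                sub[acc] = new[acc]
                self.delta[:, tc] = sub
                esub = self.eta[:, tc]
                esub[acc] += d[acc]
                self.eta[:, tc] = esub
                msub = self.mu[:, tc]
                msub[acc] *= np.exp(d[acc])
                self.mu[:, tc] = msub
            self._track("delta", int(acc.sum()), self.N * k, adapting)
        self.mu_sum = float(self.mu.sum())

    def _rescale_move(self, name: str, adapting: bool) -> None:
        """Joint scale move (field, var) -> (c field, c^2 var), c = e^z.

        Breaks the funnel between a weakly-identified field and its
        variance: the Gaussian field prior is invariant under the paired
        rescaling, so the MH log-ratio reduces to
        dloglik - 2a log c - (b/var)(c^-2 - 1) + 0   (Jacobian c^(K+2)
        cancelling the prior's c^-K and the inverse-gamma shift), with
        (a, b) the precision's Gamma prior.  Skipped when the variance is
        fixed.
        """
        cfg = self.cfg
        if (cfg.fixed_variances or {}).get(f"var_{name}") is not None:
            return
        field = getattr(self, name)
        var = getattr(self, f"var_{name}")
        z = self.scales[f"scale_{name}"] * self.rng.standard_normal()
        c = np.exp(z)
        if name == "phi":
            contrib = field[:, None] * np.ones((1, self.T))
        elif name == "xi":
            contrib = np.ones((self.N, 1)) * field[None, :]
        else:
            contrib = field
        eta_new = self.eta + (c - 1.0) * contrib
        if eta_new.max() > _ETA_MAX:
            self._track(f"scale_{name}", 0, 1, adapting)
            return
        mu_new = np.exp(eta_new)
        dll = (c - 1.0) * float((self.y * contrib).sum()) - (mu_new.sum() - self.mu_sum)
        a, b = cfg.prior_precision_shape, cfg.prior_precision_rate
        dlp = -2.0 * a * z - (b / var) * (c**-2 - 1.0)
        if np.log(self.rng.random()) < dll + dlp:
            setattr(self, name, c * field)
            setattr(self, f"var_{name}", c**2 * var)
            self.eta = eta_new
            self.mu = mu_new
            self.mu_sum = float(mu_new.sum())
            self._track(f"scale_{name}", 1, 1, adapting)
        else:
            self._track(f"scale_{name}", 0, 1, adapting)

    def _recentre(self) -> None:
        cfg = self.cfg
        if cfg.include_interaction:
            r = self.delta.mean(axis=1)
            if cfg.include_spatial and cfg.spatial_structure == "icar":
                self.delta -= r[:, None]
                self.phi += r
            # otherwise row levels stay in delta (no likelihood-invariant home)
        if cfg.include_spatial and cfg.spatial_structure == "icar" and len(self.noniso):
            m = self.phi[self.noniso].mean()
            self.phi[self.noniso] -= m
            self.alpha += m
        if cfg.include_temporal:
            m = self.xi.mean()
            self.xi -= m
            self.alpha += m

    def update_block(self, block: str, adapting: bool = False) -> float:
        before = self.accept_counts.copy()
        pb = self.propose_counts.copy()
        if block == "alpha":
            self.update_alpha(adapting)
        elif block == "beta":
            self.update_beta(adapting)
        elif block == "phi":
            self.update_phi(adapting)
        elif block == "xi":
            self.update_xi(adapting)
        elif block == "delta":
            self.update_delta(adapting)
        else:
            raise ValueError(f"unknown block {block!r}")
        acc = sum(self.accept_counts.values()) - sum(before.values())
        prop = sum(self.propose_counts.values()) - sum(pb.values())
        return acc / max(prop, 1.0)

    def update_all_variances(self) -> None:
        cfg = self.cfg
        fixed = cfg.fixed_variances or {}
        a, b = cfg.prior_precision_shape, cfg.prior_precision_rate
        if cfg.prior_only:
            # pure prior draws of the three precisions
            for name in ("var_phi", "var_xi", "var_delta"):
                if name not in fixed:
                    setattr(self, name, 1.0 / max(self.rng.gamma(a, 1.0 / b), _VAR_FLOOR))
            return
        if cfg.include_spatial and "var_phi" not in fixed:
            sh, ra = variance_posterior_params(
                "phi", self.phi, self.graph, shape=a, rate=b,
                spatial_structure=cfg.spatial_structure,
            )
            self.var_phi = 1.0 / max(self.rng.gamma(sh, 1.0 / ra), _VAR_FLOOR)
        if cfg.include_temporal and "var_xi" not in fixed:
            sh, ra = variance_posterior_params("xi", self.xi, shape=a, rate=b)
            self.var_xi = 1.0 / max(self.rng.gamma(sh, 1.0 / ra), _VAR_FLOOR)
        if cfg.include_interaction and "var_delta" not in fixed:
            sh, ra = variance_posterior_params("delta", self.delta, shape=a, rate=b)
            self.var_delta = 1.0 / max(self.rng.gamma(sh, 1.0 / ra), _VAR_FLOOR)

    def iterate(self, adapting: bool) -> None:
        cfg = self.cfg
        self.update_alpha(adapting)
        if self.P:
            self.update_beta(adapting)
        if not cfg.prior_only:
            if cfg.include_spatial:
                self.update_phi(adapting)
                self._rescale_move("phi", adapting)
            if cfg.include_temporal:
                self.update_xi(adapting)
                self._rescale_move("xi", adapting)
            if cfg.include_interaction:
                self.update_delta(adapting)
                self._rescale_move("delta", adapting)
            self._recentre()
        self.update_all_variances()

    def run(self) -> dict:
        cfg = self.cfg
        keep = cfg.samples_per_chain
        out = {
            "alpha": np.empty(keep),
            "beta": np.empty((keep, self.P)),
            "phi": np.empty((keep, self.N)),
            "xi": np.empty((keep, self.T)),
            "delta": np.empty((keep, self.N, self.T)) if cfg.store_delta else None,
            "var_phi": np.empty(keep),
            "var_xi": np.empty(keep),
            "var_delta": np.empty(keep),
        }
        total = cfg.n_burnin + keep * cfg.thin
        s = 0
        for it in range(total):
            adapting = it < cfg.n_burnin
            self.iterate(adapting)
            if adapting and (it + 1) % 50 == 0:
                self._adapt()
            if (it + 1) % 500 == 0:
                self._refresh_eta()  # kill incremental rounding drift
            if not adapting and (it - cfg.n_burnin + 1) % cfg.thin == 0:
                out["alpha"][s] = self.alpha
                out["beta"][s] = self.beta
                out["phi"][s] = self.phi
                out["xi"][s] = self.xi
                if out["delta"] is not None:
                    out["delta"][s] = self.delta
                out["var_phi"][s] = self.var_phi
                out["var_xi"][s] = self.var_xi
                out["var_delta"][s] = self.var_delta
                s += 1
        for block, rate in self.acceptance_rates().items():
            if block == "alpha":
                continue
            if rate < 0.01 or rate > 0.99:
                warnings.warn(
                    f"block {block!r} acceptance rate {rate:.3f} outside (0.01, 0.99); "
                    "proposal tuning may have failed",
                    RuntimeWarning,
                    stacklevel=2,
                )
        out["acceptance"] = self.acceptance_rates()
        return out


def update_latent_block(
    block: str,
    state: Mapping,
    panel: AreaPanel,
    graph: AdjacencyGraph,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[dict, float]:
    """One Metropolis(-within-Gibbs) sweep of a single block on a given state.

    Functional wrapper over the chain kernels, mainly for targeted tests;
    returns the new state and the sweep's acceptance fraction.
    """
    s = _Sampler(panel, graph, config, rng)
    s.load_state(state)
    acc = s.update_block(block)
    return s.dump_state(), acc


@dataclass
class PosteriorSamples:
    """Multi-chain MCMC draws with bookkeeping.

    Arrays are indexed (chain, draw, ...); ``stacked`` pools chains.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    xi: np.ndarray
    delta: np.ndarray | None
    var_phi: np.ndarray
    var_xi: np.ndarray
    var_delta: np.ndarray
    acceptance: list[dict]
    config: ModelConfig
    area_ids: list[str] = field(default_factory=list)
    years: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} draws were not stored")
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def delta_stacked(self) -> np.ndarray:
        """Pooled interaction draws; zeros when the term is inactive."""
        if self.delta is not None:
            return self.stacked("delta")
        if self.config.include_interaction:
            raise ValueError("interaction draws were not stored (store_delta=False)")
        n, t = self.phi.shape[2], self.xi.shape[2]
        return np.zeros((self.n_chains * self.n_draws, n, t))

    def linear_predictor(self, panel: AreaPanel) -> np.ndarray:
        """Per-draw eta_it, shape (draws, N, T), pooled over chains."""
        xb = np.einsum("ntp,sp->snt", panel.covariates, self.stacked("beta"))
        return (
            self.stacked("alpha")[:, None, None]
            + xb
            + self.stacked("phi")[:, :, None]
            + self.stacked("xi")[:, None, :]
            + self.delta_stacked()
        )

    def mu_draws(self, panel: AreaPanel) -> np.ndarray:
        """Per-draw expected counts mu_it, shape (draws, N, T)."""
        return np.exp(self.linear_predictor(panel))

    def save(self, path: str | Path) -> None:
        arrays = {
            k: getattr(self, k)
            for k in ("alpha", "beta", "phi", "xi", "var_phi", "var_xi", "var_delta")
        }
        if self.delta is not None:
            arrays["delta"] = self.delta
        meta = {
            "config": dataclasses.asdict(self.config),
            "acceptance": self.acceptance,
            "area_ids": self.area_ids,
            "years": None if self.years is None else np.asarray(self.years).tolist(),
            "covariate_names": self.covariate_names,
        }
        np.savez_compressed(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["_meta"]))
            return cls(
                alpha=z["alpha"],
                beta=z["beta"],
                phi=z["phi"],
                xi=z["xi"],
                delta=z["delta"] if "delta" in z.files else None,
                var_phi=z["var_phi"],
                var_xi=z["var_xi"],
                var_delta=z["var_delta"],
                acceptance=meta["acceptance"],
                config=ModelConfig(**meta["config"]),
                area_ids=meta["area_ids"],
                years=None if meta["years"] is None else np.array(meta["years"]),
                covariate_names=meta["covariate_names"],
            )


def run_mcmc(
    panel: AreaPanel, graph: AdjacencyGraph, config: ModelConfig
) -> PosteriorSamples:
    """Fit the model: independent chains from over-dispersed starts.

    Proposal adaptation is confined to burn-in; retained draws satisfy the
    active sum-to-zero constraints.  The same (panel, graph, config) always
    reproduces bit-identical chains.
    """
    if config.include_spatial and panel.n_areas < 2:
        raise ValueError("spatial CAR undefined with fewer than 2 areas")
    cmax = np.abs(panel.covariates.mean(axis=(0, 1))).max() if panel.n_covariates else 0.0
    if cmax > 1e-6:
        logger.warning(
            "covariates are not centred (max |grand mean| = %.3g); "
            "consider center_covariates() for better mixing", cmax
        )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    results = []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sampler = _Sampler(panel, graph, config, rng)
        sampler.init_state(jitter=0.1 * (1 + c))
        results.append(sampler.run())
        logger.info("chain %d/%d done; acceptance %s", c + 1, config.n_chains,
                    {k: round(v, 3) for k, v in results[-1]["acceptance"].items()})
    stack = lambda k: np.stack([r[k] for r in results])
    return PosteriorSamples(
        alpha=stack("alpha"),
        beta=stack("beta"),
        phi=stack("phi"),
        xi=stack("xi"),
        delta=stack("delta") if config.store_delta else None,
        var_phi=stack("var_phi"),
        var_xi=stack("var_xi"),
        var_delta=stack("var_delta"),
        acceptance=[r["acceptance"] for r in results],
        config=config,
        area_ids=list(panel.area_ids),
        years=panel.years.copy(),
        covariate_names=list(panel.covariate_names),
    )


def competing_model_family(
    panel: AreaPanel,
    graph: AdjacencyGraph,
    config: ModelConfig,
    variants: list[str] | None = None,
) -> dict[str, PosteriorSamples]:
    """Fit the named competing specifications for WAIC comparison.

    Variants toggle the structural flags of the full model: no space-time
    interaction, exchangeable (iid) instead of ICAR spatial effects, no
    spatial effects, no temporal trend.  A variant removing all random
    effects reduces to a plain Poisson regression and is permitted.
    """
    names = variants if variants is not None else list(MODEL_VARIANTS)
    out = {}
    for name in names:
        if name not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {name!r}; choose from {list(MODEL_VARIANTS)}")
        out[name] = run_mcmc(panel, graph, config.replace(**MODEL_VARIANTS[name]))
    return out
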