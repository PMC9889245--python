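"""Convergence and goodness-of-fit diagnostics.

Implements the split-chain Gelman-Rubin potential scale reduction factor,
the Watanabe-Akaike information criterion (WAIC) from pointwise Poisson
log-likelihoods, and posterior predictive Bayesian p-values (per-cell
discrete mid-p tail probabilities, with a chi-square discrepancy variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import poisson

from .model import PosteriorSamples
from .panel_io import AreaPanel

logger = logging.getLogger(__name__)


def gelman_rubin(chains: np.ndarray | list, split: bool = True) -> float:
    """Potential scale reduction factor (PSRF) for one scalar parameter.

    Parameters
    ----------
    chains : array-like, shape (m, n)
        m >= 2 chains of n >= 10 draws each (n >= 2 when ``split`` is
        False).  With ``split=True`` (default) each chain is halved first,
        which also detects within-chain drift.

    Returns
    -------
    float
        sqrt((n-1)/n + (m+1)/(m n) * B/W), with B the between-chain and W
        the mean within-chain variance; approaches 1 from mixed chains as
        n grows.  NaN (with a warning) when every chain has zero
        within-chain variance.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 chains of equal length")
    if split:
        if arr.shape[1] < 4:
            raise ValueError("split-chain PSRF needs chains of length >= 4")
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = arr.shape
    w = arr.var(axis=1, ddof=1).mean()
    if w == 0:
        logger.warning("zero within-chain variance in every chain; PSRF undefined")
        return float("nan")
    b = n * arr.mean(axis=1).var(ddof=1)
    return float(np.sqrt((n - 1) / n + (m + 1) / (m * n) * b / w))


def _pointwise_loglik(samples: PosteriorSamples, panel: AreaPanel) -> np.ndarray:
    """Per-draw, per-cell Poisson log-likelihood, shape (draws, N*T)."""
    mu = samples.mu_draws(panel).reshape(samples.n_chains * samples.n_draws, -1)
    y = panel.counts.reshape(-1)[None, :]
    return poisson.logpmf(y, mu)


def waic(samples: PosteriorSamples, panel: AreaPanel) -> tuple[float, pd.DataFrame]:
    """Watanabe-Akaike information criterion, deviance scale.

    WAIC = -2 (lppd - p_waic): lppd is the summed log pointwise predictive
    density (log of the posterior-mean likelihood per cell, via stabilised
    log-sum-exp) and p_waic the summed posterior variance of the pointwise
    log-likelihood.  Lower is better.  Returns the total and a pointwise
    table (area, year, lppd_i, p_waic_i, waic_i).
    """
    ll = _pointwise_loglik(samples, panel)
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    waic_i = -2.0 * (lppd_i - p_i)
    n, t = panel.counts.shape
    table = pd.DataFrame(
        {
            "area_id": np.repeat(panel.area_ids, t),
            "year": np.tile(panel.years, n),
            "lppd": lppd_i,
            "p_waic": p_i,
            "waic": waic_i,
        }
    )
    return float(waic_i.sum()), table


def bayesian_pvalue(
    samples: PosteriorSamples,
    panel: AreaPanel,
    statistic: str = "mid_p",
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, float]:
    """Posterior predictive p-values.

    statistic='mid_p' (default): per-cell discrete mid-p tail probability
    p_it = P(y_rep > y_it) + 0.5 P(y_rep = y_it) under the posterior
    predictive, computed in closed form by averaging Poisson tail
    probabilities over retained draws; 0.5 indicates a perfectly calibrated
    cell.  statistic='chi_square': a single global p-value
    P(T(y_rep, mu) >= T(y, mu)) for the chi-square discrepancy
    T = sum (y - mu)^2 / mu, estimated by drawing one replicate panel per
    retained draw (also returned per cell as the per-draw indicator mean).

    Returns (per-cell N x T array, average over cells).
    """
    mu = samples.mu_draws(panel)
    y = panel.counts[None, :, :]
    if statistic == "mid_p":
        upper = poisson.sf(y, mu)  # P(y_rep > y)
        point = poisson.pmf(y, mu)
        per_cell = (upper + 0.5 * point).mean(axis=0)
    elif statistic == "chi_square":
        rng = np.random.default_rng(rng)
        yrep = rng.poisson(mu)
        t_obs = ((panel.counts[None] - mu) ** 2 / mu).sum(axis=(1, 2))
        t_rep = ((yrep - mu) ** 2 / mu).sum(axis=(1, 2))
        p = float((t_rep >= t_obs).mean())
        per_cell = np.full(panel.counts.shape, p)
    else:
        raise ValueError("statistic must be 'mid_p' or 'chi_square'")
    return per_cell, float(per_cell.mean())


@dataclass
class FitDiagnostics:
    """Convergence and fit summary of one fitted model."""

    rhat: pd.Series
    waic: float
    waic_table: pd.DataFrame
    bayes_p: np.ndarray
    bayes_p_mean: float
    acceptance: list[dict]

    def report(self) -> str:
        lines = [
            "Fit diagnostics",
            "---------------",
            f"WAIC: {self.waic:.2f} (p_waic = {self.waic_table['p_waic'].sum():.1f})",
            f"Average Bayesian p-value (mid-p): {self.bayes_p_mean:.3f}",
            f"max split-Rhat: {self.rhat.max():.4f}",
            "Rhat by parameter:",
        ]
        lines += [f"  {k}: {v:.4f}" for k, v in self.rhat.items()]
        lines.append("Acceptance rates (chain 1):")
        lines += [f"  {k}: {v:.3f}" for k, v in self.acceptance[0].items()]
        return "\n".join(lines)


def diagnose(samples: PosteriorSamples, panel: AreaPanel) -> FitDiagnostics:
    """Compute Rhat for the scalar parameters, WAIC and Bayesian p-values."""
    def _rhat(chains: np.ndarray) -> float:
        if chains.shape[0] < 2:
            return float("nan")  # PSRF needs multiple chains
        return gelman_rubin(chains)

    if samples.n_chains < 2:
        logger.warning("single chain: Gelman-Rubin PSRF not computable, reporting NaN")
    rhat = {}
    rhat["alpha"] = _rhat(samples.alpha)
    for p, name in enumerate(samples.covariate_names or
                             [f"beta{p}" for p in range(samples.beta.shape[2])]):
        rhat[f"beta[{name}]"] = _rhat(samples.beta[:, :, p])
    cfg = samples.config
    fixed = cfg.fixed_variances or {}
    if cfg.include_spatial and "var_phi" not in fixed:
        rhat["var_phi"] = _rhat(samples.var_phi)
    if cfg.include_temporal and "var_xi" not in fixed:
        rhat["var_xi"] = _rhat(samples.var_xi)
    if cfg.include_interaction and "var_delta" not in fixed:
        rhat["var_delta"] = _rhat(samples.var_delta)
    w, table = waic(samples, panel)
    per_cell, avg = bayesian_pvalue(samples, panel)
    return FitDiagnostics(
        rhat=pd.Series(rhat),
        waic=w,
        waic_table=table,
        bayes_p=per_cell,
        bayes_p_mean=avg,
        acceptance=samples.acceptance,
    )
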