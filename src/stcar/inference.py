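"""Posterior products: marginal effects, expected counts, hotspots, trends.

Everything here is computed draw-by-draw from the retained MCMC samples and
then summarised, so every reported interval is a genuine posterior credible
interval of the quantity itself (e.g. the between-area gap in expected
counts is the posterior of the per-draw gap, not the gap of posterior
means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PosteriorSamples
from .panel_io import AreaPanel

logger = logging.getLogger(__name__)

HOTSPOT_THRESHOLD = 0.9


def _summary(draws: np.ndarray, axis: int = 0) -> dict[str, np.ndarray]:
    return {
        "mean": draws.mean(axis=axis),
        "sd": draws.std(axis=axis, ddof=1) if draws.shape[axis] > 1
        else np.zeros_like(draws.mean(axis=axis)),
        "q2.5": np.quantile(draws, 0.025, axis=axis),
        "median": np.quantile(draws, 0.5, axis=axis),
        "q97.5": np.quantile(draws, 0.975, axis=axis),
    }


def _exceed_half_ties(draws: np.ndarray, axis: int = 0) -> np.ndarray:
    """P(draw > 0) with exact zeros counted as 1/2 (tie convention)."""
    return (draws > 0).mean(axis=axis) + 0.5 * (draws == 0).mean(axis=axis)


def marginal_effects(samples: PosteriorSamples, panel: AreaPanel) -> pd.DataFrame:
    """Posterior marginal effect of each covariate on the expected count.

    Per retained draw, ME_p = (mean of mu_it over all N*T cells) * beta_p:
    the change in expected yearly events per unit change in covariate p,
    evaluated at the average fitted mean.  Returns mean, sd and 95%
    credible interval per covariate.
    """
    mu_bar = samples.mu_draws(panel).mean(axis=(1, 2))  # (draws,)
    beta = samples.stacked("beta")  # (draws, P)
    me = mu_bar[:, None] * beta
    s = _summary(me)
    names = samples.covariate_names or [f"x{p + 1}" for p in range(beta.shape[1])]
    return pd.DataFrame({"covariate": names, **{k: v for k, v in s.items()}})


def hotspot_probability(
    samples: PosteriorSamples, threshold: float = HOTSPOT_THRESHOLD
) -> pd.DataFrame:
    """Exceedance probability P(exp(phi_i) > 1) per area and hotspot flags.

    An area is flagged as having excess event frequency (after covariate
    adjustment) when the posterior probability that its spatial residual
    relative risk exp(phi_i) exceeds 1 -- equivalently phi_i > 0 -- is
    larger than the threshold (default 0.9).
    """
    phi = samples.stacked("phi")
    prob = _exceed_half_ties(phi)
    return pd.DataFrame(
        {
            "area_id": samples.area_ids or list(range(phi.shape[1])),
            "prob_exceed": prob,
            "hotspot": prob > threshold,
        }
    )


def expected_counts(
    samples: PosteriorSamples, panel: AreaPanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior summaries of mu_it and of the per-year extreme-area gap.

    The gap for year t is computed per draw as max_i mu_it - min_i mu_it
    and then summarised, so its credible interval is a proper posterior
    interval of the gap (the extreme areas may differ between draws).
    Returns (cells table, per-year gap table).
    """
    mu = samples.mu_draws(panel)  # (draws, N, T)
    s = _summary(mu)
    n, t = panel.counts.shape
    cells = pd.DataFrame(
        {
            "area_id": np.repeat(panel.area_ids, t),
            "year": np.tile(panel.years, n),
            "observed": panel.counts.reshape(-1),
            **{k: v.reshape(-1) for k, v in s.items()},
        }
    )
    gap_draws = mu.max(axis=1) - mu.min(axis=1)  # (draws, T)
    gs = _summary(gap_draws)
    gaps = pd.DataFrame({"year": panel.years, **{k: v for k, v in gs.items()}})
    return cells, gaps


def area_trend(
    samples: PosteriorSamples, panel: AreaPanel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Area-specific trends and their exceedance of the national trend.

    Each area's temporal trend is xi_t + delta_it.  Because the national
    component xi_t is common, the probability that an area's incidence
    exceeds the national one in year t is P(delta_it > 0), with exact-zero
    draws counted as 1/2 (so a model without interaction reports 0.5
    everywhere).  Returns (per-(area, year) exceedance table, national
    trend table with posterior median and 95% band of xi_t).
    """
    xi = samples.stacked("xi")
    delta = samples.delta_stacked()
    prob = _exceed_half_ties(delta)  # (N, T)
    trend_mean = (xi[:, None, :] + delta).mean(axis=0)
    n, t = prob.shape
    area_ids = samples.area_ids or list(range(n))
    years = samples.years if samples.years is not None else np.arange(t)
    trends = pd.DataFrame(
        {
            "area_id": np.repeat(area_ids, t),
            "year": np.tile(years, n),
            "trend_mean": trend_mean.reshape(-1),
            "prob_exceed_national": prob.reshape(-1),
        }
    )
    ns = _summary(xi)
    national = pd.DataFrame({"year": years, **{k: v for k, v in ns.items()}})
    return trends, national


def deprivation_gradient(
    samples: PosteriorSamples,
    panel: AreaPanel,
    covariate: str,
    years: tuple[int, int],
    offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-year slope of log expected counts against a deprivation covariate.

    For each retained draw and each selected year, the OLS slope of
    log(mu_it) on the covariate across areas; the posterior of each slope
    and of their difference (second year minus first) quantifies whether
    the socio-economic gradient has steepened.  ``offsets`` (from
    center_covariates) restores the original covariate scale for
    interpretability; the slope itself is unaffected by centring.
    """
    if covariate not in panel.covariate_names:
        raise ValueError(f"covariate {covariate!r} not in panel")
    k = panel.covariate_names.index(covariate)
    mu = samples.mu_draws(panel)
    rows = []
    slopes = {}
    for year in years:
        t = int(np.flatnonzero(panel.years == year)[0])
        x = panel.covariates[:, t, k]
        if offsets is not None:
            x = x + offsets[k]
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {covariate!r} is constant across areas in {year}")
        xc = x - x.mean()
        denom = float(xc @ xc)
        logmu = np.log(mu[:, :, t])
        sl = (logmu - logmu.mean(axis=1, keepdims=True)) @ xc / denom  # (draws,)
        slopes[year] = sl
        s = _summary(sl[:, None])
        rows.append({"quantity": f"slope_{year}", **{k_: float(v[0]) for k_, v in s.items()}})
    diff = slopes[years[1]] - slopes[years[0]]
    s = _summary(diff[:, None])
    rows.append(
        {"quantity": f"slope_{years[1]}_minus_{years[0]}",
         **{k_: float(v[0]) for k_, v in s.items()}}
    )
    return pd.DataFrame(rows)


@dataclass
class InferenceSummary:
    """Bundle of the headline posterior products of one fitted model."""

    marginal_effects: pd.DataFrame
    expected_counts: pd.DataFrame
    gaps: pd.DataFrame
    hotspots: pd.DataFrame
    trends: pd.DataFrame
    national_trend: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.marginal_effects.to_csv(outdir / "marginal_effects.csv", index=False)
        self.expected_counts.to_csv(outdir / "expected_counts.csv", index=False)
        self.gaps.to_csv(outdir / "expected_count_gaps.csv", index=False)
        self.hotspots.to_csv(outdir / "hotspots.csv", index=False)
        self.trends.to_csv(outdir / "trends.csv", index=False)
        self.national_trend.to_csv(outdir / "national_trend.csv", index=False)
        logger.info("wrote summary tables to %s", outdir)


def summarise(
    samples: PosteriorSamples,
    panel: AreaPanel,
    hotspot_threshold: float = HOTSPOT_THRESHOLD,
) -> InferenceSummary:
    """All posterior products in one pass."""
    cells, gaps = expected_counts(samples, panel)
    trends, national = area_trend(samples, panel)
    return InferenceSummary(
        marginal_effects=marginal_effects(samples, panel),
        expected_counts=cells,
        gaps=gaps,
        hotspots=hotspot_probability(samples, hotspot_threshold),
        trends=trends,
        national_trend=national,
    )
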