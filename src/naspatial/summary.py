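"""Posterior summaries: mean coefficients, credible intervals, RR transforms.

The exposure coefficient beta_x lives on the log-rate scale, so its
posterior draws translate into the quantities usually reported for areal
exposure effects:

* 95% equal-tailed credible interval (sample quantiles, linear
  interpolation);
* percent change per unit exposure, (1 - exp(beta)) * 100, read as a
  decrease when positive;
* geometric-mean relative risk exp(mean beta) — the geometric mean of the
  exp(beta) draws;
* the population-average exposure–response curve: a kernel density of the
  exponentiated draws, i.e. the posterior of the multiplicative risk
  change per unit increase in exposure.

All summaries are pure functions of the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .exceptions import InputError
from .standardize import round_half_away

__all__ = [
    "EffectSummary",
    "DensityEstimate",
    "credible_interval",
    "percent_change",
    "geometric_mean_rr",
    "exposure_response_density",
    "summarize_effect",
]


@dataclass(frozen=True)
class EffectSummary:
    """Posterior summary of one exposure/covariate coefficient."""

    parameter: str
    mean: float
    ci_lower: float
    ci_upper: float
    percent_change: float
    rr: float
    significant: bool
    level: float = 0.95

    def rounded(self) -> dict:
        """Display-rounded values: coefficients 3 dp, RR 2 dp, percent 1 dp."""
        return {
            "parameter": self.parameter,
            "mean": round_half_away(self.mean, 3),
            "ci_lower": round_half_away(self.ci_lower, 3),
            "ci_upper": round_half_away(self.ci_upper, 3),
            "percent_change": round_half_away(self.percent_change, 1),
            "rr": round_half_away(self.rr, 2),
            "significant": self.significant,
            "level": self.level,
        }


@dataclass(frozen=True)
class DensityEstimate:
    """Serialized kernel density (or point mass) of exponentiated draws."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    point_mass: float | None = None

    def integral(self) -> float:
        if self.point_mass is not None:
            return 1.0
        return float(np.trapezoid(self.density, self.grid))


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval via sample quantiles (linear interp)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InputError("empty draws")
    if not (0.0 < level < 1.0):
        raise InputError(f"level must be in (0,1), got {level}")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return float(lo), float(hi)


def percent_change(beta: float) -> float:
    """(1 - exp(beta)) * 100: the percent decrease per unit exposure."""
    if not np.isfinite(beta):
        raise InputError(f"beta must be finite, got {beta}")
    return (1.0 - np.exp(beta)) * 100.0


def geometric_mean_rr(draws) -> float:
    """exp(mean beta) — the geometric mean of the relative-risk draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InputError("empty draws")
    return float(np.exp(draws.mean()))


def exposure_response_density(draws, grid_size: int = 512) -> DensityEstimate:
    """Kernel density of exp(beta) draws (population-average exposure response).

    Degenerate (constant) draws yield a point-mass representation rather
    than a crash.  The automatic grid extends five bandwidths beyond the
    draw range so the density integrates to 1 within 1e-3.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise InputError("empty draws")
    rr = np.exp(draws)
    if np.ptp(rr) == 0.0:
        val = float(rr[0])
        return DensityEstimate(
            grid=np.array([val]), density=np.array([np.inf]), bandwidth=0.0, point_mass=val
        )
    kde = gaussian_kde(rr)
    bw = float(kde.factor * rr.std(ddof=1))
    grid = np.linspace(rr.min() - 5 * bw, rr.max() + 5 * bw, grid_size)
    return DensityEstimate(grid=grid, density=kde(grid), bandwidth=bw)


def summarize_effect(draws, parameter: str = "beta_x", level: float = 0.95) -> EffectSummary:
    """Bundle mean, CI, percent change, geometric-mean RR and significance.

    ``draws`` is a :class:`~naspatial.bym.PosteriorDraws`, a DataFrame with
    a column named ``parameter``, or a plain vector of draws.
    """
    if hasattr(draws, "get") and hasattr(draws, "params"):
        vec = draws.get(parameter)
    elif hasattr(draws, "columns"):
        if parameter not in draws.columns:
            raise InputError(f"unknown parameter {parameter!r}")
        vec = draws[parameter].to_numpy(dtype=float)
    else:
        vec = np.asarray(draws, dtype=float)
    if vec.size == 0:
        raise InputError("empty draws")
    mean = float(vec.mean())
    lo, hi = credible_interval(vec, level)
    return EffectSummary(
        parameter=parameter,
        mean=mean,
        ci_lower=lo,
        ci_upper=hi,
        percent_change=percent_change(mean),
        rr=geometric_mean_rr(vec),
        significant=bool(lo > 0.0 or hi < 0.0),
        level=level,
    )
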