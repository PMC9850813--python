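"""Besag–York–Mollié (BYM) Poisson disease-mapping model.

The outcome model for area i is

    Y_i ~ Poisson(mu_i),
    log mu_i = log E_i + beta0 + beta_x * X_i + gamma' Z_i + phi_i + theta_i,

with E_i the indirectly standardized expected count (offset), X_i the
exposure (physicians per 10,000 — left on its natural scale so beta_x is
the log-rate change per one physician per 10,000), Z_i covariates, phi a
spatially structured random effect with a CAR prior on the contiguity
graph (intrinsic by default, sum-to-zero per connected component), and
theta an unstructured iid N(0, sigma_theta^2) effect.

Coefficients get N(0, 10^2) priors; the variance hyperparameters get
weakly-informative inverse-gamma(1, 0.01) priors.  Sampling is
Metropolis-within-Gibbs (see :mod:`naspatial._mcmc`); draws after burn-in
are returned in a :class:`PosteriorDraws`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _mcmc
from ._mcmc import AcceptanceTracker, GaussianLikelihood, PoissonLikelihood
from .exceptions import InputError, ParameterError
from .graph import AreaGraph

__all__ = ["BymSpec", "PosteriorDraws", "poisson_loglik", "linear_predictor", "fit_bym"]


@dataclass
class BymSpec:
    """Configuration of a BYM fit.

    ``covariates=None`` auto-selects every column prefixed ``z_``.
    ``iterations`` counts total sweeps; draws after ``burn_in`` are saved.
    """

    exposure: str = "exposure"
    covariates: Sequence[str] | None = None
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    coef_prior_sd: float = 10.0
    variance_prior_shape: float = 1.0
    variance_prior_rate: float = 0.01
    car_variant: str = "icar"  # "icar" or "proper"
    car_alpha: float = 0.9  # propriety parameter, proper variant only
    include_structured: bool = True
    include_unstructured: bool = True
    likelihood: str = "poisson"  # "gaussian" enables the conjugate test hook
    gaussian_sigma: float = 1.0
    field_update: str = "block"  # "block" or "single"
    translation_moves: bool = True  # directional moves along weakly identified trade-offs
    save_random_effects: bool = True

    def validate(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ParameterError(
                f"need iterations > burn_in >= 0, got {self.iterations}, {self.burn_in}"
            )
        if not self.coef_prior_sd > 0:
            raise ParameterError("coefficient prior sd must be positive")
        if self.car_variant not in ("icar", "proper"):
            raise ParameterError(f"unknown CAR variant {self.car_variant!r}")
        if self.likelihood not in ("poisson", "gaussian"):
            raise ParameterError(f"unknown likelihood {self.likelihood!r}")
        if self.field_update not in ("block", "single"):
            raise ParameterError(f"unknown field_update {self.field_update!r}")


@dataclass
class PosteriorDraws:
    """Post-burn-in posterior draws with chain metadata.

    ``params`` has one row per saved iteration and one column per scalar
    parameter; ``random_effects`` maps effect names to (n_draws, n_areas)
    arrays aligned with ``area_ids``.
    """

    params: pd.DataFrame
    random_effects: dict[str, np.ndarray] = dc_field(repr=False)
    area_ids: tuple[str, ...]
    seed: int
    iterations: int
    burn_in: int
    acceptance: dict[str, float]
    model: str

    def __post_init__(self) -> None:
        expected = self.iterations - self.burn_in
        if len(self.params) != expected:
            raise InputError(
                f"saved draws ({len(self.params)}) != iterations - burn_in ({expected})"
            )

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def get(self, parameter: str) -> np.ndarray:
        if parameter not in self.params.columns:
            raise InputError(
                f"unknown parameter {parameter!r}; available: {list(self.params.columns)}"
            )
        return self.params[parameter].to_numpy()


def poisson_loglik(y, expected, eta) -> float:
    """Poisson log-likelihood sum_i [Y_i(log E_i + eta_i) - E_i e^eta_i - log Y_i!]."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise InputError("expected counts must be positive")
    lik = PoissonLikelihood(y, np.log(expected))
    return lik.loglik(np.asarray(eta, dtype=float))


def linear_predictor(draw: Mapping, data: pd.DataFrame, exposure: str = "exposure") -> np.ndarray:
    """eta_i = beta0 + beta_x X_i + gamma' Z_i + phi_i + theta_i for one draw.

    ``draw`` maps parameter names to values: scalar ``beta0``/``beta_x``,
    optional ``gamma_<col>`` scalars, optional vectors ``phi``/``theta``/``u``.
    """
    n = len(data)
    eta = np.full(n, float(draw.get("beta0", 0.0)))
    if "beta_x" in draw:
        if exposure not in data.columns:
            raise InputError(f"data lacks exposure column {exposure!r}")
        eta = eta + float(draw["beta_x"]) * data[exposure].to_numpy(dtype=float)
    for name, value in draw.items():
        if name.startswith("gamma_"):
            col = name[len("gamma_"):]
            if col not in data.columns:
                raise InputError(f"data lacks covariate column {col!r}")
            eta = eta + float(value) * data[col].to_numpy(dtype=float)
    for name in ("phi", "theta", "u"):
        if name in draw:
            vec = np.asarray(draw[name], dtype=float)
            if vec.shape != (n,):
                raise InputError(f"{name} has shape {vec.shape}, expected ({n},)")
            eta = eta + vec
    return eta


def _design(data: pd.DataFrame, spec: BymSpec) -> tuple[np.ndarray, list[str]]:
    if spec.exposure not in data.columns:
        raise InputError(f"data lacks exposure column {spec.exposure!r}")
    covs = (
        sorted(c for c in data.columns if c.startswith("z_"))
        if spec.covariates is None
        else list(spec.covariates)
    )
    for c in covs:
        if c not in data.columns:
            raise InputError(f"data lacks covariate column {c!r}")
    cols = [np.ones(len(data)), data[spec.exposure].to_numpy(dtype=float)]
    names = ["beta0", "beta_x"]
    for c in covs:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(f"gamma_{c}")
    return np.column_stack(cols), names


def _check_alignment(data: pd.DataFrame, graph: AreaGraph) -> None:
    if len(data) != graph.n_areas:
        raise InputError(
            f"data has {len(data)} rows but graph has {graph.n_areas} areas"
        )
    if "area_id" in data.columns:
        ids = tuple(str(a) for a in data["area_id"])
        if ids != graph.area_ids:
            raise InputError("data area ordering does not match graph area_ids")


def _make_likelihood(data: pd.DataFrame, spec: BymSpec):
    y = data["y_late"].to_numpy()
    expected = data["expected"].to_numpy(dtype=float)
    if np.any(~np.isfinite(expected)) or np.any(expected <= 0):
        raise InputError("expected counts must be finite and positive")
    log_offset = np.log(expected)
    if spec.likelihood == "gaussian":
        return GaussianLikelihood(y, log_offset, spec.gaussian_sigma)
    return PoissonLikelihood(y, log_offset)


def fit_bym(data: pd.DataFrame, graph: AreaGraph, spec: BymSpec | None = None) -> PosteriorDraws:
    """Fit the BYM model by MCMC and return post-burn-in draws.

    ``data`` must share the graph's area ordering (checked via ``area_id``
    when present) and carry columns ``y_late``, ``expected``, the exposure
    and any covariates.  Reproducible given ``spec.seed``.
    """
    spec = spec or BymSpec()
    spec.validate()
    _check_alignment(data, graph)
    lik = _make_likelihood(data, spec)
    rng = np.random.default_rng(spec.seed)
    n = graph.n_areas

    A, names = _design(data, spec)
    p = A.shape[1]
    prior_prec = np.eye(p) / spec.coef_prior_sd**2

    deg = graph.degrees
    mask = deg > 0  # structured effect lives on non-isolated nodes
    n_struct = int(mask.sum())
    labels = graph.component_labels[mask]
    n_comp_struct = len(np.unique(labels)) if n_struct else 0
    if spec.car_variant == "icar":
        rank = n_struct - n_comp_struct
    else:
        rank = n_struct
    W_sub = graph.W[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
    M_sub = np.diag(deg[mask]) - W_sub.toarray() * (
        1.0 if spec.car_variant == "icar" else spec.car_alpha
    )
    color_classes = (
        _mcmc.greedy_coloring(W_sub.tocsr()) if spec.field_update == "single" else None
    )

    # start beta and phi at their conditional modes so quadratic proposals
    # operate in the high-mass region from the first sweep
    midx = np.flatnonzero(mask)
    beta = _mcmc.optimize_coefficients(lik, np.zeros(n), A, np.zeros(p), prior_prec)
    phi = np.zeros(n)
    theta = np.zeros(n)
    sigma2_theta = 0.1
    tau_phi = 1.0
    if spec.include_structured and n_struct:
        phi_sub0 = _mcmc.optimize_field(
            _subset_likelihood(lik, midx),
            (A @ beta)[midx],
            np.zeros(n_struct),
            np.zeros(n_struct),
            tau_phi * M_sub,
        )
        if spec.car_variant == "icar":
            for c in np.unique(labels):
                sel = labels == c
                phi_sub0[sel] -= phi_sub0[sel].mean()
        phi[midx] = phi_sub0
    a0 = spec.variance_prior_shape
    b0 = spec.variance_prior_rate

    n_save = spec.iterations - spec.burn_in
    out_params = np.empty((n_save, p + 3))
    phi_draws = np.empty((n_save, n)) if spec.save_random_effects else None
    theta_draws = np.empty((n_save, n)) if spec.save_random_effects else None
    tracker = AcceptanceTracker()
    shift_scale = _mcmc.AdaptiveScale(init=0.05)

    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(spec.iterations):
            base = phi + theta
            beta = _mcmc.newton_block_coefficients(
                lik, base, A, beta, prior_prec, rng, tracker, "beta"
            )
            xb = A @ beta

            if spec.include_unstructured:
                theta = _mcmc.newton_sites_independent(
                    lik, xb + phi, theta,
                    np.zeros(n), np.full(n, 1.0 / sigma2_theta),
                    rng, tracker, "theta",
                )
                ss = float(theta @ theta)
                sigma2_theta = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ss))

            if spec.include_structured and n_struct:
                base_phi = (xb + theta)[midx]
                sub_lik = _subset_likelihood(lik, midx)
                Q = tau_phi * M_sub
                if spec.field_update == "block":
                    phi_sub = _mcmc.newton_block_field(
                        sub_lik, base_phi, phi[midx], np.zeros(n_struct),
                        Q, rng, tracker, "phi",
                    )
                else:
                    phi_sub = _mcmc.newton_sites_colored(
                        sub_lik, base_phi, phi[midx], np.zeros(n_struct),
                        sp.csr_array(Q), color_classes, rng, tracker, "phi",
                    )
                if spec.car_variant == "icar":
                    for c in np.unique(labels):
                        sel = labels == c
                        phi_sub = phi_sub.copy()
                        phi_sub[sel] -= phi_sub[sel].mean()
                phi = np.zeros(n)
                phi[midx] = phi_sub
                qf = float(phi[midx] @ (M_sub @ phi[midx]))
                tau_phi = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * qf))

                if spec.translation_moves:
                    # directional move along the exposure/structured-effect
                    # trade-off: eta is (nearly) invariant, so the move mixes
                    # the weakly identified beta_x direction at prior cost
                    eps = shift_scale.value * rng.standard_normal()
                    xm = A[midx, 1]
                    xc = xm.copy()
                    for c in np.unique(labels):
                        sel = labels == c
                        xc[sel] -= xm[sel].mean()
                    beta_p = beta.copy()
                    beta_p[1] += eps
                    beta_p[0] -= eps * float(A[:, 1].mean())
                    phi_p = phi.copy()
                    phi_p[midx] = phi[midx] - eps * xc
                    eta_cur = A @ beta + phi + theta
                    eta_p = A @ beta_p + phi_p + theta
                    qf_p = float(phi_p[midx] @ (M_sub @ phi_p[midx]))
                    lp_diff = (
                        lik.loglik(eta_p) - lik.loglik(eta_cur)
                        - 0.5 * tau_phi * (qf_p - qf)
                        - 0.5 * float(beta_p @ (prior_prec @ beta_p) - beta @ (prior_prec @ beta))
                    )
                    ap = float(np.exp(min(lp_diff, 0.0))) if np.isfinite(lp_diff) else 0.0
                    if rng.random() < ap:
                        beta, phi = beta_p, phi_p
                        tracker.record("shift_beta_x", 1.0)
                    else:
                        tracker.record("shift_beta_x", 0.0)
                    shift_scale.adapt(ap, frozen=t >= spec.burn_in)

            eta = xb + phi + theta
            ll = lik.loglik(eta)
            if not np.isfinite(ll):
                raise RuntimeError(f"divergent chain: non-finite log-likelihood at iteration {t}")

            if t >= spec.burn_in:
                s = t - spec.burn_in
                out_params[s, :p] = beta
                out_params[s, p] = sigma2_theta
                out_params[s, p + 1] = tau_phi
                out_params[s, p + 2] = ll
                if spec.save_random_effects:
                    phi_draws[s] = phi
                    theta_draws[s] = theta

    params = pd.DataFrame(out_params, columns=names + ["sigma2_theta", "tau_phi", "loglik"])
    random_effects = {}
    if spec.save_random_effects:
        random_effects = {"phi": phi_draws, "theta": theta_draws}
    return PosteriorDraws(
        params=params,
        random_effects=random_effects,
        area_ids=graph.area_ids,
        seed=spec.seed,
        iterations=spec.iterations,
        burn_in=spec.burn_in,
        acceptance=tracker.rates(),
        model="bym",
    )


def _subset_likelihood(lik, idx: np.ndarray):
    """Restrict a likelihood object to a subset of areas."""
    if isinstance(lik, PoissonLikelihood):
        return PoissonLikelihood(lik.y[idx], lik.log_offset[idx])
    return GaussianLikelihood(lik.y[idx], lik.log_offset[idx], lik.sigma)
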