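"""Neighbourhood-adjustment (NA) model for unmeasured spatial confounding.

An unobserved, spatially structured confounder U correlated with the
exposure X biases naive areal regressions: the part of U's effect that
co-varies with X is attributed to X.  The NA model de-biases the exposure
coefficient by modelling exposure and confounder jointly and imputing U as
missing data inside the Gibbs sampler.  The implemented joint coupling is
linear-Gaussian through the neighbourhood smoother S:

    U | X ~ N(delta * S^order X, Q_U^-1),   Q_U = tau_U (D - alpha_U W),

so the confounding bias functional is explicit, B(X) = delta * S^order X,
and the outcome model becomes

    log mu_i = log E_i + beta0 + beta_x X_i + gamma' Z_i + U_i.

Because U's conditional mean tracks the *neighbourhood-smoothed* exposure,
the coefficient beta_x is identified by the fine-scale variation of X (the
component the smoother removes).  This is the scale assumption: the
exposure field must carry spatial variation at least as large in range as
the confounder, plus a fine-scale component not shared with it.  When a
generator config violates the assumption the package warns rather than
failing (see :mod:`naspatial.simulate`).

delta and tau_U have conjugate updates (Gaussian and gamma); U is updated
by quadratic-approximation Metropolis–Hastings, either as one block via a
dense Cholesky or site-wise over a graph colouring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _mcmc
from ._mcmc import AcceptanceTracker, batch_means_mcse
from .bym import BymSpec, PosteriorDraws, _check_alignment, _design, _make_likelihood
from .exceptions import ContractError, InputError
from .graph import AreaGraph, SmootherMatrix, neighbourhood_smoother, proper_car_precision

__all__ = [
    "NaSpec",
    "LatentConfounderLaw",
    "joint_exposure_confounder_model",
    "impute_confounder",
    "fit_na",
    "bias_gap",
]


@dataclass
class NaSpec(BymSpec):
    """Configuration of an NA fit (extends :class:`BymSpec`).

    ``confounder_alpha`` is the propriety parameter of U's proper CAR prior
    (its spatial range); ``exposure_alpha`` records the exposure field's
    assumed range for the identification check; ``smoother_order`` is the
    number of neighbourhood-averaging passes in the coupling mean;
    ``couple=False`` fixes delta = 0, giving the unadjusted spatial model.
    """

    confounder_variant: str = "proper"
    confounder_alpha: float = 0.5
    exposure_alpha: float = 0.95
    smoother_order: int = 1
    delta_prior_sd: float = 10.0
    couple: bool = True
    residual_effects: bool = False  # retain BYM-style theta alongside U
    enforce_identification: bool = True

    def validate(self) -> None:  # noqa: D102 - extends parent contract
        super().validate()
        if self.confounder_variant != "proper":
            raise ContractError(
                "the latent confounder requires a proper CAR prior; "
                f"got variant {self.confounder_variant!r}"
            )
        if not (0.0 <= self.confounder_alpha < 1.0):
            raise InputError(f"confounder_alpha must be in [0,1), got {self.confounder_alpha}")
        if self.enforce_identification and self.exposure_alpha < self.confounder_alpha:
            warnings.warn(
                "identification assumption at risk: exposure spatial range "
                f"(alpha={self.exposure_alpha}) is smaller than the confounder's "
                f"(alpha={self.confounder_alpha}); the de-biased estimate may degrade",
                stacklevel=2,
            )


@dataclass(frozen=True)
class LatentConfounderLaw:
    """Conditional law U | X ~ N(mean, Q^-1) under the joint model."""

    mean: np.ndarray = dc_field(repr=False)
    Q: sp.csr_array = dc_field(repr=False)
    delta: float
    smoother: SmootherMatrix = dc_field(repr=False)
    smoothed_exposure: np.ndarray = dc_field(repr=False)


def joint_exposure_confounder_model(
    X: np.ndarray,
    graph: AreaGraph,
    spec: NaSpec,
    delta: float,
    tau_u: float = 1.0,
) -> LatentConfounderLaw:
    """Conditional distribution of the latent confounder given exposure.

    U | X ~ N(delta * S^order X, (tau_U (D - alpha_U W))^-1); delta governs
    the exposure–confounder correlation the joint model permits.
    """
    X = np.asarray(X, dtype=float)
    if X.shape != (graph.n_areas,):
        raise InputError(f"X has shape {X.shape}, expected ({graph.n_areas},)")
    if spec.confounder_variant != "proper":
        raise ContractError("confounder prior must be proper")
    S = neighbourhood_smoother(graph, spec.smoother_order)
    v = S.apply(X)
    Q = proper_car_precision(graph, tau_u, spec.confounder_alpha).Q
    return LatentConfounderLaw(
        mean=delta * v, Q=Q, delta=float(delta), smoother=S, smoothed_exposure=v
    )


def impute_confounder(
    lik,
    base_eta: np.ndarray,
    u: np.ndarray,
    law: LatentConfounderLaw,
    rng: np.random.Generator,
    tracker: AcceptanceTracker | None = None,
    method: str = "block",
    color_classes=None,
) -> np.ndarray:
    """One Gibbs sweep of the latent confounder U from its full conditional.

    The full conditional is proportional to lik(base_eta + U) * N(U | mean,
    Q^-1); updates use Gaussian proposals from a local quadratic
    approximation, either one n-dimensional block (dense Cholesky) or
    site-by-site over a graph colouring.
    """
    tracker = tracker or AcceptanceTracker()
    if not np.all(np.isfinite(u)):
        raise RuntimeError("non-finite confounder state entering imputation")
    if method == "block":
        return _mcmc.newton_block_field(
            lik, base_eta, u, law.mean, law.Q.toarray(), rng, tracker, "u"
        )
    if method == "single":
        if color_classes is None:
            color_classes = _mcmc.greedy_coloring(law.smoother.graph.W.tocsr())
        return _mcmc.newton_sites_colored(
            lik, base_eta, u, law.mean, law.Q, color_classes, rng, tracker, "u"
        )
    raise InputError(f"unknown update method {method!r}")


def fit_na(data: pd.DataFrame, graph: AreaGraph, spec: NaSpec | None = None) -> PosteriorDraws:
    """Fit the neighbourhood-adjustment model by MCMC.

    Returns draws of the exposure coefficient purged of the confounding
    bias B(X) = delta * S^order X, plus delta, tau_u and the imputed U.
    Reproducible given ``spec.seed``.
    """
    spec = spec or NaSpec()
    spec.validate()
    _check_alignment(data, graph)
    lik = _make_likelihood(data, spec)
    rng = np.random.default_rng(spec.seed)
    n = graph.n_areas

    A, names = _design(data, spec)
    p = A.shape[1]
    prior_prec = np.eye(p) / spec.coef_prior_sd**2

    X = data[spec.exposure].to_numpy(dtype=float)
    S = neighbourhood_smoother(graph, spec.smoother_order)
    v = S.apply(X)
    M = proper_car_precision(graph, 1.0, spec.confounder_alpha).Q  # unit-tau structure
    M_dense = M.toarray()
    color_classes = (
        _mcmc.greedy_coloring(graph.W.tocsr()) if spec.field_update == "single" else None
    )

    # start beta and U at their conditional modes (quadratic proposals need
    # the chain in the high-mass region from the first sweep)
    beta = _mcmc.optimize_coefficients(lik, np.zeros(n), A, np.zeros(p), prior_prec)
    u = _mcmc.optimize_field(lik, A @ beta, np.zeros(n), np.zeros(n), M_dense)
    theta = np.zeros(n)
    delta = 0.0
    tau_u = 1.0
    sigma2_theta = 0.1
    a0 = spec.variance_prior_shape
    b0 = spec.variance_prior_rate
    delta_prec0 = 1.0 / spec.delta_prior_sd**2

    n_save = spec.iterations - spec.burn_in
    extra = 3 if spec.residual_effects else 2
    out_params = np.empty((n_save, p + extra + 1))
    u_draws = np.empty((n_save, n)) if spec.save_random_effects else None
    theta_draws = (
        np.empty((n_save, n)) if (spec.save_random_effects and spec.residual_effects) else None
    )
    tracker = AcceptanceTracker()
    shift0 = _mcmc.AdaptiveScale(init=0.05)
    shiftx = _mcmc.AdaptiveScale(init=0.05)

    vMv = float(v @ (M_dense @ v))

    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(spec.iterations):
            base = u + theta
            beta = _mcmc.newton_block_coefficients(
                lik, base, A, beta, prior_prec, rng, tracker, "beta"
            )
            xb = A @ beta

            # --- latent confounder sweep ---
            mu = delta * v
            if spec.field_update == "block":
                u = _mcmc.newton_block_field(
                    lik, xb + theta, u, mu, tau_u * M_dense, rng, tracker, "u"
                )
            else:
                u = _mcmc.newton_sites_colored(
                    lik, xb + theta, u, mu, sp.csr_array(tau_u * M_dense),
                    color_classes, rng, tracker, "u",
                )
            if not np.all(np.isfinite(u)):
                raise RuntimeError(f"non-finite confounder imputation at iteration {t}")

            # --- conjugate coupling coefficient ---
            if spec.couple:
                prec = tau_u * vMv + delta_prec0
                mean = tau_u * float(v @ (M_dense @ u)) / prec
                delta = mean + rng.standard_normal() / np.sqrt(prec)

            # --- conjugate precision of U ---
            r = u - delta * v
            qf = float(r @ (M_dense @ r))
            tau_u = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * qf))

            # --- directional translation moves ---
            # eta is invariant along (beta0, U) and (beta_x, delta, U)
            # shifts, so these scalar moves mix the weakly identified
            # trade-off directions at prior cost only
            if spec.translation_moves:
                for kind, scale in (("shift_beta0", shift0), ("shift_beta_x", shiftx)):
                    eps = scale.value * rng.standard_normal()
                    beta_p = beta.copy()
                    if kind == "shift_beta0":
                        beta_p[0] += eps
                        u_p = u - eps
                        delta_p = delta
                    else:
                        beta_p[1] += eps
                        u_p = u - eps * X
                        delta_p = delta - eps if spec.couple else delta
                    eta_cur = A @ beta + u + theta
                    eta_p = A @ beta_p + u_p + theta
                    r_cur = u - delta * v
                    r_p = u_p - delta_p * v
                    lp_diff = (
                        lik.loglik(eta_p) - lik.loglik(eta_cur)
                        - 0.5 * tau_u * (float(r_p @ (M_dense @ r_p)) - float(r_cur @ (M_dense @ r_cur)))
                        - 0.5 * float(beta_p @ (prior_prec @ beta_p) - beta @ (prior_prec @ beta))
                        - 0.5 * delta_prec0 * (delta_p**2 - delta**2)
                    )
                    ap = float(np.exp(min(lp_diff, 0.0))) if np.isfinite(lp_diff) else 0.0
                    if rng.random() < ap:
                        beta, u, delta = beta_p, u_p, delta_p
                        tracker.record(kind, 1.0)
                    else:
                        tracker.record(kind, 0.0)
                    scale.adapt(ap, frozen=t >= spec.burn_in)

            # --- optional residual iid effects ---
            if spec.residual_effects:
                theta = _mcmc.newton_sites_independent(
                    lik, xb + u, theta, np.zeros(n),
                    np.full(n, 1.0 / sigma2_theta), rng, tracker, "theta",
                )
                ss = float(theta @ theta)
                sigma2_theta = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ss))

            eta = xb + u + theta
            ll = lik.loglik(eta)
            if not np.isfinite(ll):
                raise RuntimeError(f"divergent chain: non-finite log-likelihood at iteration {t}")

            if t >= spec.burn_in:
                s = t - spec.burn_in
                out_params[s, :p] = beta
                out_params[s, p] = delta
                out_params[s, p + 1] = tau_u
                if spec.residual_effects:
                    out_params[s, p + 2] = sigma2_theta
                out_params[s, -1] = ll
                if spec.save_random_effects:
                    u_draws[s] = u
                    if theta_draws is not None:
                        theta_draws[s] = theta

    columns = names + ["delta", "tau_u"]
    if spec.residual_effects:
        columns.append("sigma2_theta")
    columns.append("loglik")
    params = pd.DataFrame(out_params, columns=columns)
    random_effects = {}
    if spec.save_random_effects:
        random_effects["u"] = u_draws
        if theta_draws is not None:
            random_effects["theta"] = theta_draws
    return PosteriorDraws(
        params=params,
        random_effects=random_effects,
        area_ids=graph.area_ids,
        seed=spec.seed,
        iterations=spec.iterations,
        burn_in=spec.burn_in,
        acceptance=tracker.rates(),
        model="na",
    )


def bias_gap(draws_bym: PosteriorDraws, draws_na: PosteriorDraws, parameter: str = "beta_x"):
    """Difference of posterior means (BYM minus NA) with a Monte-Carlo SE.

    A positive gap means the unadjusted estimate sits above the de-biased
    one — the direction expected when an unobserved spatial confounder
    positively coupled to exposure biases the naive estimator upward.
    """
    a = draws_bym.get(parameter)
    b = draws_na.get(parameter)
    if a.size == 0 or b.size == 0:
        raise InputError("empty draws")
    gap = float(a.mean() - b.mean())
    se = float(np.hypot(batch_means_mcse(a), batch_means_mcse(b)))
    return gap, se
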