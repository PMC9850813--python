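"""Internal MCMC machinery shared by the BYM and neighbourhood-adjustment fits.

All non-conjugate blocks (regression coefficients, structured/unstructured
random effects, the latent confounder) are updated by Metropolis–Hastings
with a Gaussian proposal built from a local quadratic (Newton) approximation
of the log full conditional at the current state.  For a Poisson log-link
likelihood these proposals are close to the true conditionals, so
acceptance rates sit near 1 and draws are nearly independent; with the
Gaussian test-hook likelihood the proposal IS the exact conditional.

Two update schedules exist for latent fields:

* ``block`` — one n-dimensional proposal per sweep with Hessian
  ``diag(h) + Q`` factorised densely (n is a few hundred here);
* ``single`` — per-site proposals swept over a greedy graph colouring so
  each colour class updates in a vectorised pass.

Conjugate blocks (variance/precision parameters, the coupling coefficient
delta) are drawn exactly by Gibbs elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.special import gammaln

from .exceptions import InputError

_ETA_MAX = 500.0  # log-mean beyond this is treated as divergence


class PoissonLikelihood:
    """Poisson counts with a log link and a log-offset: Y_i ~ Pois(E_i e^eta_i)."""

    def __init__(self, y, log_offset):
        y = np.asarray(y)
        if not np.all(np.isfinite(y)) or np.any(y < 0) or np.any(y != np.floor(y)):
            raise InputError("Poisson outcome must be nonnegative integers")
        self.y = y.astype(float)
        self.log_offset = np.asarray(log_offset, dtype=float)
        self._lgamma = gammaln(self.y + 1.0)

    def loglik(self, eta) -> float:
        log_mu = self.log_offset + eta
        return float(np.sum(self.y * log_mu - np.exp(log_mu) - self._lgamma))

    def pointwise(self, eta) -> np.ndarray:
        log_mu = self.log_offset + eta
        return self.y * log_mu - np.exp(log_mu) - self._lgamma

    def grad_hess(self, eta):
        """First/negative-second derivative of the per-site loglik wrt eta_i."""
        lam = np.exp(self.log_offset + eta)
        return self.y - lam, lam


class GaussianLikelihood:
    """Gaussian test hook: Y_i ~ N(log_offset_i + eta_i, sigma^2).

    Keeps the offset-plus-linear-predictor structure of the Poisson model so
    samplers can be exercised against closed-form conjugate posteriors.
    """

    def __init__(self, y, log_offset, sigma: float):
        if not sigma > 0:
            raise InputError(f"sigma must be positive, got {sigma}")
        self.y = np.asarray(y, dtype=float)
        self.log_offset = np.asarray(log_offset, dtype=float)
        self.sigma = float(sigma)
        self._prec = 1.0 / sigma**2

    def loglik(self, eta) -> float:
        return float(np.sum(self.pointwise(eta)))

    def pointwise(self, eta) -> np.ndarray:
        r = self.y - self.log_offset - eta
        return -0.5 * self._prec * r**2 - 0.5 * np.log(2.0 * np.pi) - np.log(self.sigma)

    def grad_hess(self, eta):
        r = self.y - self.log_offset - eta
        return self._prec * r, np.full_like(r, self._prec)


@dataclass
class AcceptanceTracker:
    accepted: dict = field(default_factory=dict)
    attempted: dict = field(default_factory=dict)

    def record(self, block: str, accepted: float, attempted: float = 1.0) -> None:
        self.accepted[block] = self.accepted.get(block, 0.0) + accepted
        self.attempted[block] = self.attempted.get(block, 0.0) + attempted

    def rates(self) -> dict:
        return {
            k: self.accepted[k] / max(self.attempted[k], 1.0) for k in self.attempted
        }


def _mvn_chol(H: np.ndarray):
    """Cholesky of a dense SPD matrix; raises LinAlgError on failure."""
    return sla.cho_factor(H, lower=True)


def _logdet_from_chol(cf) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(cf[0]))))


def newton_block_coefficients(lik, base_eta, A, beta, prior_prec, rng, tracker, name):
    """One MH update of a coefficient block with design matrix A.

    Full conditional: lik(base_eta + A beta) * N(beta | 0, prior_prec^-1).
    Proposal: N(beta + H^-1 g, H^-1) with g, H from the quadratic
    approximation at the current point; corrected by the reverse proposal.
    """

    def local(b):
        eta = base_eta + A @ b
        g, h = lik.grad_hess(eta)
        grad = A.T @ g - prior_prec @ b
        H = (A * h[:, None]).T @ A + prior_prec
        lp = lik.loglik(eta) - 0.5 * float(b @ (prior_prec @ b))
        return lp, grad, H

    lp0, g0, H0 = local(beta)
    cf0 = _mvn_chol(H0)
    mean0 = beta + sla.cho_solve(cf0, g0)
    z = rng.standard_normal(beta.size)
    prop = mean0 + sla.solve_triangular(cf0[0], z, lower=True, trans="T")
    lq_fwd = 0.5 * _logdet_from_chol(cf0) - 0.5 * float((prop - mean0) @ (H0 @ (prop - mean0)))

    lp1, g1, H1 = local(prop)
    try:
        cf1 = _mvn_chol(H1)
    except np.linalg.LinAlgError:
        tracker.record(name, 0.0)
        return beta
    mean1 = prop + sla.cho_solve(cf1, g1)
    lq_rev = 0.5 * _logdet_from_chol(cf1) - 0.5 * float((beta - mean1) @ (H1 @ (beta - mean1)))

    log_alpha = (lp1 - lp0) + (lq_rev - lq_fwd)
    if np.log(rng.random()) < log_alpha:
        tracker.record(name, 1.0)
        return prop
    tracker.record(name, 0.0)
    return beta


def newton_block_field(lik, base_eta, v, prior_mean, Q_dense, rng, tracker, name):
    """One MH block update of a latent field v with Gaussian prior N(m, Q^-1).

    The likelihood sees eta = base_eta + v.  Hessian diag(h) + Q is dense
    (n at most a few hundred in this package).
    """

    def local(x):
        eta = base_eta + x
        g, h = lik.grad_hess(eta)
        d = x - prior_mean
        grad = g - Q_dense @ d
        lp = lik.loglik(eta) - 0.5 * float(d @ (Q_dense @ d))
        return lp, grad, h

    lp0, g0, h0 = local(v)
    H0 = Q_dense + np.diag(h0)
    cf0 = _mvn_chol(H0)
    mean0 = v + sla.cho_solve(cf0, g0)
    z = rng.standard_normal(v.size)
    prop = mean0 + sla.solve_triangular(cf0[0], z, lower=True, trans="T")
    d0 = prop - mean0
    lq_fwd = 0.5 * _logdet_from_chol(cf0) - 0.5 * float(d0 @ (H0 @ d0))

    lp1, g1, h1 = local(prop)
    H1 = Q_dense + np.diag(h1)
    try:
        cf1 = _mvn_chol(H1)
    except np.linalg.LinAlgError:
        tracker.record(name, 0.0)
        return v
    mean1 = prop + sla.cho_solve(cf1, g1)
    d1 = v - mean1
    lq_rev = 0.5 * _logdet_from_chol(cf1) - 0.5 * float(d1 @ (H1 @ d1))

    log_alpha = (lp1 - lp0) + (lq_rev - lq_fwd)
    if np.log(rng.random()) < log_alpha:
        tracker.record(name, 1.0)
        return prop
    tracker.record(name, 0.0)
    return v


def newton_sites_independent(lik, base_eta, v, prior_mean, prior_prec_diag, rng, tracker, name):
    """Vectorised per-site MH for a field whose conditional factorises.

    Valid when the prior precision is diagonal given the rest of the state
    (iid unstructured effects): every site's full conditional is
    independent, so simultaneous per-site accept/reject is exact Gibbs.
    """
    eta0 = base_eta + v
    g_lik, h_lik = lik.grad_hess(eta0)
    d = v - prior_mean
    g = g_lik - prior_prec_diag * d
    h = h_lik + prior_prec_diag
    mean0 = v + g / h
    prop = mean0 + rng.standard_normal(v.size) / np.sqrt(h)

    eta1 = base_eta + prop
    g1_lik, h1_lik = lik.grad_hess(eta1)
    d1 = prop - prior_mean
    g1 = g1_lik - prior_prec_diag * d1
    h1 = h1_lik + prior_prec_diag
    mean1 = prop + g1 / h1

    lp0 = lik.pointwise(eta0) - 0.5 * prior_prec_diag * d**2
    lp1 = lik.pointwise(eta1) - 0.5 * prior_prec_diag * d1**2
    lq_fwd = 0.5 * np.log(h) - 0.5 * h * (prop - mean0) ** 2
    lq_rev = 0.5 * np.log(h1) - 0.5 * h1 * (v - mean1) ** 2

    log_alpha = (lp1 - lp0) + (lq_rev - lq_fwd)
    accept = np.log(rng.random(v.size)) < log_alpha
    out = np.where(accept, prop, v)
    tracker.record(name, float(accept.sum()), float(v.size))
    return out


def greedy_coloring(W) -> list[np.ndarray]:
    """Greedy colouring of an adjacency matrix; returns index arrays per colour."""
    n = W.shape[0]
    indptr, indices = W.indptr, W.indices
    colors = np.full(n, -1, dtype=int)
    for i in np.argsort(-np.diff(indptr)):  # highest degree first
        nb_colors = set(colors[indices[indptr[i]:indptr[i + 1]]])
        c = 0
        while c in nb_colors:
            c += 1
        colors[i] = c
    return [np.flatnonzero(colors == c) for c in range(colors.max() + 1)]


def newton_sites_colored(lik, base_eta, v, prior_mean, Q_sparse, color_classes, rng, tracker, name):
    """Single-site quadratic-proposal MH swept over graph-colour classes.

    Within a colour class no two sites are adjacent (Q off-diagonals zero),
    so their full conditionals do not involve one another and the class
    updates in one vectorised pass.
    """
    v = v.copy()
    Qdiag = Q_sparse.diagonal()
    for idx in color_classes:
        r = Q_sparse @ (v - prior_mean)
        cond_prec = Qdiag[idx]
        cond_mean = prior_mean[idx] - (r[idx] - cond_prec * (v[idx] - prior_mean[idx])) / cond_prec

        eta_full = base_eta + v
        lam_g, lam_h = lik.grad_hess(eta_full)
        d = v[idx] - cond_mean
        g = lam_g[idx] - cond_prec * d
        h = lam_h[idx] + cond_prec
        mean0 = v[idx] + g / h
        prop = mean0 + rng.standard_normal(idx.size) / np.sqrt(h)

        eta_prop = eta_full.copy()
        eta_prop[idx] = base_eta[idx] + prop
        g1_lik, h1_lik = lik.grad_hess(eta_prop)
        d1 = prop - cond_mean
        g1 = g1_lik[idx] - cond_prec * d1
        h1 = h1_lik[idx] + cond_prec
        mean1 = prop + g1 / h1

        lp0 = lik.pointwise(eta_full)[idx] - 0.5 * cond_prec * d**2
        lp1 = lik.pointwise(eta_prop)[idx] - 0.5 * cond_prec * d1**2
        lq_fwd = 0.5 * np.log(h) - 0.5 * h * (prop - mean0) ** 2
        lq_rev = 0.5 * np.log(h1) - 0.5 * h1 * (v[idx] - mean1) ** 2

        accept = np.log(rng.random(idx.size)) < (lp1 - lp0) + (lq_rev - lq_fwd)
        v[idx] = np.where(accept, prop, v[idx])
        tracker.record(name, float(accept.sum()), float(idx.size))
    return v


class AdaptiveScale:
    """Robbins–Monro adapted random-walk scale, frozen after burn-in."""

    def __init__(self, init: float = 0.05, target: float = 0.44):
        self._log_s = float(np.log(init))
        self.target = target
        self._t = 0

    @property
    def value(self) -> float:
        return float(np.exp(self._log_s))

    def adapt(self, accept_prob: float, frozen: bool) -> None:
        self._t += 1
        if not frozen:
            self._log_s += (accept_prob - self.target) / self._t**0.6
            self._log_s = float(np.clip(self._log_s, -12.0, 6.0))


def optimize_coefficients(lik, base_eta, A, beta0, prior_prec, iters=50, tol=1e-8):
    """Damped-Newton maximization of a coefficient block's log conditional.

    Used to initialize the chain at the conditional mode: quadratic
    proposals are only well behaved once the state is in the high-mass
    region (far from it the reverse-proposal correction rejects forever).
    """
    beta = np.asarray(beta0, dtype=float).copy()

    def logpost(b):
        return lik.loglik(base_eta + A @ b) - 0.5 * float(b @ (prior_prec @ b))

    lp = logpost(beta)
    for _ in range(iters):
        eta = base_eta + A @ beta
        g, h = lik.grad_hess(eta)
        grad = A.T @ g - prior_prec @ beta
        H = (A * h[:, None]).T @ A + prior_prec
        try:
            step = sla.cho_solve(_mvn_chol(H), grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        while t > 1e-6:
            cand = beta + t * step
            lp_c = logpost(cand)
            if np.isfinite(lp_c) and lp_c >= lp:
                beta, lp = cand, lp_c
                break
            t *= 0.5
        else:
            break
        if float(np.abs(t * step).max()) < tol:
            break
    return beta


def optimize_field(lik, base_eta, v0, prior_mean, Q_dense, iters=50, tol=1e-8):
    """Damped-Newton maximization of a latent field's log conditional."""
    v = np.asarray(v0, dtype=float).copy()

    def logpost(x):
        d = x - prior_mean
        return lik.loglik(base_eta + x) - 0.5 * float(d @ (Q_dense @ d))

    lp = logpost(v)
    for _ in range(iters):
        g, h = lik.grad_hess(base_eta + v)
        grad = g - Q_dense @ (v - prior_mean)
        H = Q_dense + np.diag(h)
        try:
            step = sla.cho_solve(_mvn_chol(H), grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        while t > 1e-6:
            cand = v + t * step
            lp_c = logpost(cand)
            if np.isfinite(lp_c) and lp_c >= lp:
                v, lp = cand, lp_c
                break
            t *= 0.5
        else:
            break
        if float(np.abs(t * step).max()) < tol:
            break
    return v


def batch_means_mcse(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean via batch means."""
    draws = np.asarray(draws, dtype=float)
    n = draws.size
    if n < 4:
        return float(np.std(draws, ddof=1) / np.sqrt(max(n, 1)))
    b = max(int(np.floor(np.sqrt(n))), 2)
    m = n // b
    means = draws[: m * b].reshape(m, b).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(m))
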