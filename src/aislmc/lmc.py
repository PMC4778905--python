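"""Tempered Langevin Monte Carlo (simplified-manifold MALA) transition kernel.

One kernel step targets the tempered density f_beta(w) = p(y|w)^beta p(w).
The proposal is a Gaussian drifted along the tempered gradient and
preconditioned by the tempered curvature,

    C = (Lambda + beta F)^-1,    m = w + h C g_beta,

with Lambda the prior precision, F the Fisher information at the current
point and h a fixed drift step (0.5 throughout): the proposal is the local
Gauss-Newton Gaussian approximation of the tempered target, centred at a
half-damped Newton step.  The Metropolis-Hastings
correction evaluates the reverse proposal density with (m, C) rebuilt at the
proposed point, which makes the kernel exactly f_beta-invariant despite the
position-dependent preconditioner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import linalg

from .base import BayesianModel

logger = logging.getLogger(__name__)

_JITTER_LADDER = (1e-8, 1e-6, 1e-4)


@dataclass
class TemperedState:
    """Cached quantities of one point of a trajectory at inverse temperature beta."""

    w: np.ndarray
    beta: float
    log_lik: float          # untempered log p(y|w); may be -inf on failure
    grad_log_lik: np.ndarray
    fisher: np.ndarray
    log_prior: float
    grad_log_prior: np.ndarray
    accepted: bool = True

    @property
    def log_joint(self) -> float:
        """Tempered log joint beta * log p(y|w) + log p(w)."""
        if self.beta == 0.0:
            return self.log_prior
        return self.beta * self.log_lik + self.log_prior

    @property
    def grad(self) -> np.ndarray:
        return self.beta * self.grad_log_lik + self.grad_log_prior

    def at_beta(self, beta: float) -> "TemperedState":
        """Same point, retargeted at a different temperature (caches reused)."""
        return replace(self, beta=float(beta))


@dataclass(frozen=True)
class ProposalParams:
    """Gaussian proposal N(m, C) with its Cholesky factor cached."""

    m: np.ndarray
    C: np.ndarray
    chol: np.ndarray  # lower Cholesky of C
    h: float

    def logpdf(self, x: np.ndarray) -> float:
        d = np.asarray(x, dtype=float) - self.m
        z = linalg.solve_triangular(self.chol, d, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(self.chol)))
        return float(-0.5 * (d.size * np.log(2 * np.pi) + logdet + z @ z))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.m.size)
        return self.m + self.chol @ z


def make_state(model: BayesianModel, w: np.ndarray, beta: float) -> TemperedState:
    """Evaluate likelihood, gradient and Fisher at ``w`` and cache them."""
    w = np.asarray(w, dtype=float)
    ll, g, F = model.lik_grad_fisher(w)
    if not np.isfinite(ll):
        ll = -np.inf
        g = np.zeros(model.n_params)
        F = np.zeros((model.n_params, model.n_params))
    return TemperedState(
        w=w, beta=float(beta), log_lik=float(ll),
        grad_log_lik=np.asarray(g, dtype=float),
        fisher=np.asarray(F, dtype=float),
        log_prior=model.prior.logpdf(w),
        grad_log_prior=model.prior.grad_logpdf(w),
    )


def build_proposal(state: TemperedState, prior_precision: np.ndarray,
                   h: float = 0.5) -> ProposalParams:
    """Drifted preconditioned proposal at ``state``.

    Falls back to an escalating jitter (1e-8, 1e-6, 1e-4 of mean diagonal
    scale) if Lambda + beta F is numerically indefinite; each occurrence is
    logged.
    """
    P = prior_precision + state.beta * state.fisher
    P = 0.5 * (P + P.T)
    dim = P.shape[0]
    scale = np.trace(P) / dim
    chol_P = None
    for eps in (0.0,) + _JITTER_LADDER:
        try:
            chol_P = linalg.cholesky(P + eps * scale * np.eye(dim), lower=True)
            if eps > 0:
                logger.warning("proposal precision regularised with jitter %.0e", eps)
            break
        except linalg.LinAlgError:
            continue
    if chol_P is None:
        raise linalg.LinAlgError("proposal precision not positive definite even "
                                 "after maximal jitter")
    C = linalg.cho_solve((chol_P, True), np.eye(dim))
    C = 0.5 * (C + C.T)
    m = state.w + h * C @ state.grad
    return ProposalParams(m=m, C=C, chol=linalg.cholesky(C, lower=True), h=h)


def lmc_step(state: TemperedState, model: BayesianModel,
             rng: np.random.Generator, h: float = 0.5,
             proposal: Optional[ProposalParams] = None) -> TemperedState:
    """One MALA step leaving f_beta invariant.

    Returns the new state (``accepted=True``) or the input state with
    ``accepted=False``.  A failed likelihood evaluation at the proposal
    results in automatic rejection.
    """
    Lam = model.prior.precision
    fwd = proposal if proposal is not None else build_proposal(state, Lam, h)
    w_star = fwd.sample(rng)
    cand = make_state(model, w_star, state.beta)
    if not np.isfinite(cand.log_joint):
        logger.debug("proposal rejected: evaluation failure at beta=%.4g", state.beta)
        return replace(state, accepted=False)
    rev = build_proposal(cand, Lam, h)
    log_r = (cand.log_joint - state.log_joint
             + rev.logpdf(state.w) - fwd.logpdf(w_star))
    if np.log(rng.uniform()) < log_r:
        return replace(cand, accepted=True)
    return replace(state, accepted=False)
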