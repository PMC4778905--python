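"""Regression test models: conjugate linear, squared-coefficient, approach-to-limit.

The linear model carries exact conjugate formulas for its posterior and
marginal likelihood, which serve as the analytic oracle for the samplers.
The squared-coefficient model is deliberately multimodal (predictions depend
on the coefficients only through their squares, so every sign flip of a
parameter leaves the fit unchanged).  The approach-to-limit model describes a
voltage ramping from -60 mV towards -60 + V_a with time constant tau, with
both parameters estimated on the log scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

from .base import BayesianModel, Dataset, GaussianPrior

# exp() clamp: keeps predictions finite in far prior tails instead of overflowing
_EXP_MAX = 700.0


def _safe_exp(x):
    x = np.asarray(x, dtype=float)
    if np.any(x > _EXP_MAX):
        warnings.warn("exp() argument clamped to avoid overflow", RuntimeWarning,
                      stacklevel=2)
    return np.exp(np.minimum(x, _EXP_MAX))


class GaussianRegressionModel(BayesianModel):
    """Shared Gauss-Newton plumbing for regression models with IID noise.

    Subclasses provide ``predict(w)`` and ``jacobian(w)``; the log-likelihood,
    its gradient J^T r / sigma^2 and the Fisher information J^T J / sigma^2
    follow from the Gaussian observation model.
    """

    def predict(self, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def _sigma(self) -> float:
        return float(self.data.noise_sd[0])

    def log_lik(self, w: np.ndarray) -> float:
        r = self.data.y - self.predict(w)
        n = r.size
        s2 = self._sigma ** 2
        return float(-0.5 * n * np.log(2 * np.pi * s2) - 0.5 * (r @ r) / s2)

    def grad_log_lik(self, w: np.ndarray) -> np.ndarray:
        r = self.data.y - self.predict(w)
        return self.jacobian(w).T @ r / self._sigma ** 2

    def fisher(self, w: np.ndarray) -> np.ndarray:
        J = self.jacobian(w)
        return J.T @ J / self._sigma ** 2


class LinearRegressionModel(GaussianRegressionModel):
    """y = X w + e with e ~ N(0, sigma^2 I) and a Gaussian prior on w.

    Fully conjugate: posterior and marginal likelihood are available in closed
    form and used as oracles for the sampling machinery.
    """

    def __init__(self, data: Dataset, prior: GaussianPrior | None = None,
                 prior_variance: float = 10.0):
        if data.X is None:
            raise ValueError("linear regression requires a design matrix in data.X")
        p = data.X.shape[1]
        if prior is None:
            prior = GaussianPrior(np.zeros(p), np.eye(p) / prior_variance)
        super().__init__(prior, data)

    def predict(self, w):
        return self.data.X @ np.asarray(w, dtype=float)

    def jacobian(self, w):
        return self.data.X

    # -- conjugate oracles ------------------------------------------------------
    def analytic_posterior(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mean, precision): precision = Lambda + X^T X / sigma^2."""
        X, y = self.data.X, self.data.y
        s2 = self._sigma ** 2
        prec = self.prior.precision + X.T @ X / s2
        rhs = self.prior.precision @ self.prior.mean + X.T @ y / s2
        chol = linalg.cholesky(prec, lower=True)
        mean = linalg.cho_solve((chol, True), rhs)
        return mean, prec

    def analytic_log_evidence(self) -> float:
        """log N(y; X mu, sigma^2 I + X Lambda^-1 X^T), the exact marginal."""
        X, y = self.data.X, self.data.y
        n = y.size
        S = self._sigma ** 2 * np.eye(n) + X @ self.prior.covariance @ X.T
        chol = linalg.cholesky(S, lower=True)
        d = y - X @ self.prior.mean
        z = linalg.solve_triangular(chol, d, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return float(-0.5 * (n * np.log(2 * np.pi) + logdet + z @ z))

    def sample_posterior(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Exact posterior draws (used e.g. as input to the harmonic-mean estimator)."""
        mean, prec = self.analytic_posterior()
        chol = linalg.cholesky(prec, lower=True)
        z = rng.standard_normal((size, mean.size))
        return mean + linalg.solve_triangular(chol, z.T, lower=True, trans="T").T


class SquaredCoeffModel(GaussianRegressionModel):
    """y = X (w * w) + e: regression coefficients are the squares of w.

    The posterior has 2^p symmetric modes (one per sign pattern of w), making
    the model a minimal testbed for multimodal inference.
    """

    def __init__(self, data: Dataset, prior: GaussianPrior | None = None,
                 prior_variance: float = 10.0):
        if data.X is None:
            raise ValueError("squared-coefficient model requires data.X")
        p = data.X.shape[1]
        if prior is None:
            prior = GaussianPrior(np.zeros(p), np.eye(p) / prior_variance)
        super().__init__(prior, data)

    def predict(self, w):
        w = np.asarray(w, dtype=float)
        return self.data.X @ (w * w)

    def jacobian(self, w):
        w = np.asarray(w, dtype=float)
        return 2.0 * self.data.X * w[None, :]


class ApproachModel(GaussianRegressionModel):
    """Exponential approach to limit: y(t) = -60 + V_a (1 - exp(-t/tau)) + e.

    Parameters are w1 = log(tau), w2 = log(V_a).  The reduced variant keeps
    only V_a and predicts the constant -60 + V_a over the whole interval.

    The default prior mean [3, 1.6] with precision diag(16, 16) pairs the
    first prior component with w1 = log(tau) as printed in the source
    configuration; ``prior_order="swapped"`` pairs it with log(V_a) instead
    (3 ~ log 30 and 1.6 ~ log 8 suggest that reading), since the original
    ordering is ambiguous.
    """

    def __init__(self, data: Dataset, reduced: bool = False,
                 prior: GaussianPrior | None = None, prior_order: str = "as_printed"):
        if data.t is None:
            raise ValueError("approach model requires a time grid in data.t")
        self.reduced = bool(reduced)
        if prior is None:
            mu = np.array([3.0, 1.6])
            if prior_order == "swapped":
                mu = mu[::-1]
            elif prior_order != "as_printed":
                raise ValueError("prior_order must be 'as_printed' or 'swapped'")
            if reduced:
                # reduced model keeps only w = log(V_a): second component
                prior = GaussianPrior(mu[1:], np.array([[16.0]]))
            else:
                prior = GaussianPrior(mu, np.diag([16.0, 16.0]))
        super().__init__(prior, data)

    def predict(self, w):
        w = np.asarray(w, dtype=float)
        t = self.data.t
        if self.reduced:
            va = _safe_exp(w[0])
            return np.full_like(t, -60.0 + va)
        tau, va = _safe_exp(w[0]), _safe_exp(w[1])
        return -60.0 + va * (1.0 - np.exp(-t / tau))

    def jacobian(self, w):
        w = np.asarray(w, dtype=float)
        t = self.data.t
        if self.reduced:
            va = _safe_exp(w[0])
            return np.full((t.size, 1), va)
        tau, va = _safe_exp(w[0]), _safe_exp(w[1])
        ex = np.exp(-t / tau)
        # d/dw1 = tau * d/dtau,  d/dw2 = va * d/dva  (log-scale chain rule)
        return np.column_stack([-va * ex * t / tau, va * (1.0 - ex)])


def squared_predict(w, X):
    """Prediction of the squared-coefficient model: X (w * w)."""
    w = np.asarray(w, dtype=float)
    return np.asarray(X, dtype=float) @ (w * w)


def approach_predict(w, t, reduced: bool = False):
    """Prediction of the approach-to-limit model on time grid ``t``."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    t = np.asarray(t, dtype=float)
    if reduced:
        return np.full_like(t, -60.0 + _safe_exp(w[0]))
    tau, va = _safe_exp(w[0]), _safe_exp(w[1])
    return -60.0 + va * (1.0 - np.exp(-t / tau))
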