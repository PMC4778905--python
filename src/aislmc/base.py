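"""Model contract shared by every sampler and every concrete model.

A :class:`BayesianModel` bundles a Gaussian prior with callbacks for the
log-likelihood, its gradient and the Fisher information, all expressed on an
unconstrained parameter scale ``w``.  Constrained physiological or structural
quantities live inside model internals; samplers only ever see ``w``.

Evaluation failures (ODE blow-up, overflow) are signalled by a ``-inf``
log-likelihood together with an :class:`EvaluationFailure` warning rather than
an exception, so that a Metropolis step can reject the offending proposal and
the annealing trajectory stays alive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg


class EvaluationFailure(UserWarning):
    """A likelihood evaluation failed (solver divergence, overflow).

    Distinct from an ordinarily small density: the evaluation itself could not
    be completed.  Carriers return ``-inf`` so Metropolis-Hastings rejects.
    """


@dataclass(frozen=True)
class GaussianPrior:
    """Multivariate Gaussian prior with mean ``mean`` and *precision* ``precision``.

    The precision parameterisation follows the N(x; m, Lambda) convention used
    throughout the package: ``Lambda`` is the inverse covariance.
    """

    mean: np.ndarray
    precision: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        prec = np.atleast_2d(np.asarray(self.precision, dtype=float))
        if prec.shape != (mean.size, mean.size):
            raise ValueError("precision shape does not match mean length")
        if not np.allclose(prec, prec.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        # Cholesky doubles as the positive-definiteness check.
        chol = linalg.cholesky(prec, lower=True)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "_chol", chol)

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def covariance(self) -> np.ndarray:
        return linalg.cho_solve((self._chol, True), np.eye(self.dim))

    @property
    def log_det_precision(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    def logpdf(self, w: np.ndarray) -> float:
        d = np.asarray(w, dtype=float) - self.mean
        quad = float(d @ self.precision @ d)
        return 0.5 * (self.log_det_precision - self.dim * np.log(2 * np.pi) - quad)

    def grad_logpdf(self, w: np.ndarray) -> np.ndarray:
        return -self.precision @ (np.asarray(w, dtype=float) - self.mean)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
        """Draw from N(mean, precision^-1) via the precision Cholesky."""
        n = 1 if size is None else int(size)
        z = rng.standard_normal((n, self.dim))
        # solve L^T x = z  =>  cov(x) = (L L^T)^-1 = precision^-1
        x = linalg.solve_triangular(self._chol, z.T, lower=True, trans="T").T
        draws = x + self.mean
        return draws[0] if size is None else draws


@dataclass
class Dataset:
    """Observed data with known observation-noise standard deviation(s).

    ``y`` is a vector (regression) or an (outputs x samples) matrix
    (multi-channel time series).  ``X`` holds a design matrix, ``t`` a time
    grid; concrete models use whichever applies.  Noise variances are treated
    as known and fixed, so ``noise_sd`` is part of the data, not a parameter.
    """

    y: np.ndarray
    noise_sd: np.ndarray
    X: Optional[np.ndarray] = None
    t: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.noise_sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be strictly positive")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)

    # -- CSV + JSON sidecar I/O -------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write observations as CSV (columns = outputs) + a JSON sidecar.

        The sidecar records noise_sd, the time grid or design matrix, and any
        metadata (e.g. the generating truth for synthetic data).
        """
        path = Path(path)
        y = np.atleast_2d(self.y)
        if self.y.ndim == 1:
            frame = pd.DataFrame({"y": self.y})
        else:
            frame = pd.DataFrame(self.y.T, columns=[f"y{i+1}" for i in range(y.shape[0])])
        frame.to_csv(path, index=False)
        sidecar = {
            "noise_sd": self.noise_sd.tolist(),
            "t": None if self.t is None else self.t.tolist(),
            "X": None if self.X is None else self.X.tolist(),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        y = frame.to_numpy().T
        if y.shape[0] == 1:
            y = y[0]
        return cls(
            y=y,
            noise_sd=np.asarray(sidecar["noise_sd"], dtype=float),
            X=None if sidecar["X"] is None else np.asarray(sidecar["X"], dtype=float),
            t=None if sidecar["t"] is None else np.asarray(sidecar["t"], dtype=float),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class BayesianModel:
    """Abstract base: Gaussian prior + likelihood callbacks on the w scale.

    Subclasses implement :meth:`log_lik`, :meth:`grad_log_lik` and
    :meth:`fisher`; everything else (log joint, tempered quantities, the
    ``fit`` entry point) is provided here.
    """

    prior: GaussianPrior
    data: Dataset

    def __init__(self, prior: GaussianPrior, data: Dataset):
        self.prior = prior
        self.data = data

    @property
    def n_params(self) -> int:
        return self.prior.dim

    # -- subclass responsibilities ---------------------------------------------
    def log_lik(self, w: np.ndarray) -> float:
        raise NotImplementedError

    def grad_log_lik(self, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def fisher(self, w: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def lik_grad_fisher(self, w: np.ndarray):
        """(log_lik, grad, Fisher) in one call.

        Models where all three derive from a single expensive forward pass
        (the neural mass model) override this to share the computation.
        """
        return self.log_lik(w), self.grad_log_lik(w), self.fisher(w)

    # -- shared machinery -------------------------------------------------------
    def sample_prior(self, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
        return self.prior.sample(rng, size)

    def log_joint(self, w: np.ndarray, beta: float = 1.0) -> float:
        """Tempered log joint  beta * log p(y|w) + log p(w);  beta=1 untempered.

        At beta = 0 this is exactly the log prior, regardless of the
        likelihood (including failed evaluations, which never occur at
        beta = 0 because the likelihood is not evaluated).
        """
        w = np.asarray(w, dtype=float)
        if w.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {w.size}")
        lp = self.prior.logpdf(w)
        if beta == 0.0:
            return lp
        return beta * self.log_lik(w) + lp

    def grad_log_joint(self, w: np.ndarray, beta: float = 1.0) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        gp = self.prior.grad_logpdf(w)
        if beta == 0.0:
            return gp
        return beta * self.grad_log_lik(w) + gp

    def fit(self, n_temps: int = 512, n_traj: int = 32, *, order: int = 5,
            step_size: float = 0.5, seed: int = 0, n_boot: int = 1000,
            n_jobs: int = 1):
        """Run annealed importance sampling; returns an :class:`~aislmc.ais.AISResults`.

        Defaults follow the reference configuration: J=512 temperatures on a
        5th-order geometric ladder, I=32 trajectories, MALA step size h=0.5,
        1000 bootstrap resamples for the evidence interval.
        """
        from .ais import make_schedule, run_ais

        schedule = make_schedule(n_temps, order=order)
        return run_ais(self, schedule, n_traj=n_traj, seed=seed,
                       step_size=step_size, n_boot=n_boot, n_jobs=n_jobs)

    def _failed(self, msg: str) -> float:
        warnings.warn(msg, EvaluationFailure, stacklevel=3)
        return -np.inf
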