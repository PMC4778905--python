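"""Seeded generators for every simulated dataset design used by the models.

Each generator returns a :class:`~aislmc.base.Dataset` whose ``meta`` carries
the generating truth and configuration, so parameter-recovery experiments can
be rerun without stored fixture files.

Default settings are the study conditions: 7 orthonormal DCT regressors over
20 points with noise sd 0.2 for the linear design; the first two DCT columns
with truth w = (2, 2) and noise sd 0.5 for the squared-coefficient design;
V_a = 30, tau = 8 with unit noise variance for the approach-to-limit curve;
and the two-region neural mass model at w_a12 = w_a21 = 1 (others 0) with
observation noise sd 0.01 per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .base import Dataset
from .neural_mass import FULL_PARAMS, REDUCED_PARAMS, NMMConfig, integrate_nmm


def dct_basis(n: int, p: int) -> np.ndarray:
    """First ``p`` columns of the orthonormal type-II DCT basis over ``n`` points.

    Column k (k = 0..p-1) is cos(pi k (2i+1) / (2n)) scaled to unit norm, so
    the first column is constant and columns are mutually orthogonal.
    """
    if p > n:
        raise ValueError("cannot take more basis columns than points")
    i = np.arange(n)
    cols = np.cos(np.pi * np.outer(2 * i + 1, np.arange(p)) / (2 * n))
    cols *= np.sqrt(1.0 / n) * np.where(np.arange(p) == 0, 1.0, np.sqrt(2.0))
    return cols


def gen_linear(seed: int = 0, n: int = 20, p: int = 7, sigma: float = 0.2,
               prior_variance: float = 10.0) -> Dataset:
    """Linear regression data y = X beta + e with beta drawn from the prior."""
    rng = np.random.default_rng(seed)
    X = dct_basis(n, p)
    beta = rng.normal(0.0, np.sqrt(prior_variance), size=p)
    y = X @ beta + rng.normal(0.0, sigma, size=n)
    return Dataset(y=y, noise_sd=sigma, X=X,
                   meta={"truth": beta, "model": "linear", "seed": seed})


def gen_squared(seed: int = 0, n: int = 20, sigma: float = 0.5,
                truth=(2.0, 2.0)) -> Dataset:
    """Squared-coefficient data on the first two DCT columns."""
    rng = np.random.default_rng(seed)
    X = dct_basis(n, 2)
    w = np.asarray(truth, dtype=float)
    y = X @ (w * w) + rng.normal(0.0, sigma, size=n)
    return Dataset(y=y, noise_sd=sigma, X=X,
                   meta={"truth": w, "model": "squared", "seed": seed})


def gen_approach(seed: int = 0, t: Optional[np.ndarray] = None, v_a: float = 30.0,
                 tau: float = 8.0, sigma: float = 1.0) -> Dataset:
    """Approach-to-limit voltage curve at the stated truth.

    The observation grid defaults to t = 1..20 in unit steps.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(1.0, 21.0) if t is None else np.asarray(t, dtype=float)
    y = -60.0 + v_a * (1.0 - np.exp(-t / tau)) + rng.normal(0.0, sigma, size=t.size)
    truth = np.array([np.log(tau), np.log(v_a)])  # (w1, w2) on the log scale
    return Dataset(y=y, noise_sd=sigma, t=t,
                   meta={"truth": truth, "model": "approach", "seed": seed,
                         "v_a": v_a, "tau": tau})


@dataclass(frozen=True)
class SNRSpec:
    """Signal-to-noise target: sd of the noise-free region-2 signal over noise sd.

    The resulting sigma_s = sd(region-2 signal) / snr is applied to both
    observed channels.
    """

    snr: float

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def sigma_for(self, signal_region2: np.ndarray) -> float:
        return float(np.std(np.asarray(signal_region2, dtype=float)) / self.snr)


def gen_nmm(seed: int = 0, sigma_s: Optional[float] = 0.01,
            snr: Optional[SNRSpec | float] = None, full: bool = True,
            config: Optional[NMMConfig] = None,
            truth_w: Optional[np.ndarray] = None) -> Dataset:
    """Two-region neural mass time series at the generating truth.

    The default truth sets the extrinsic connection parameters to 1 on the
    unconstrained scale (strong forward and backward connections) and all
    other parameters to 0.  ``full=False`` generates from the architecture
    without the backward connection.  Noise sd is either given directly
    (``sigma_s``) or derived from a target SNR on region 2.
    """
    config = config if config is not None else NMMConfig()
    names = FULL_PARAMS if full else REDUCED_PARAMS
    if truth_w is None:
        truth_w = np.array([1.0 if n in ("a12", "a21") else 0.0 for n in names])
    truth_w = np.asarray(truth_w, dtype=float)
    traj = integrate_nmm(truth_w, config, backward=full)
    if traj is None:
        raise RuntimeError("NMM integration failed at the generating truth")
    if snr is not None:
        spec = snr if isinstance(snr, SNRSpec) else SNRSpec(float(snr))
        sigma = spec.sigma_for(traj.y_hat[1])
    elif sigma_s is not None:
        sigma = float(sigma_s)
    else:
        raise ValueError("specify either sigma_s or snr")
    if sigma < 0:
        raise ValueError("sigma_s must be non-negative")
    config = NMMConfig(**{**_config_kwargs(config), "sigma_s": (sigma, sigma)})
    rng = np.random.default_rng(seed)
    y = traj.y_hat + (rng.normal(0.0, sigma, size=traj.y_hat.shape)
                      if sigma > 0 else 0.0)
    return Dataset(y=y, noise_sd=max(sigma, np.finfo(float).tiny), t=config.t,
                   meta={"truth": truth_w, "model": "nmm", "seed": seed,
                         "full": full, "sigma_s": sigma,
                         "config": _config_kwargs(config)})


def _config_kwargs(config: NMMConfig) -> dict:
    return {
        "H_e": config.H_e, "H_i": config.H_i,
        "tau_e": config.tau_e, "tau_i": config.tau_i,
        "delta_intra": config.delta_intra,
        "input_peak": config.input_peak, "input_width": config.input_width,
        "input_amplitude": config.input_amplitude,
        "t": config.t, "sigma_s": tuple(config.sigma_s),
        "rtol": config.rtol, "atol": config.atol,
        "defaults": dict(config.defaults),
    }
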