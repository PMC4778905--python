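"""Run diagnostics: weight summaries, acceptance profiles, normality, recovery.

The importance-weight distribution is summarised by its entropy in bits
(maximum log2 I for I trajectories) and by I_q, the count of normalised
weights above 0.01.  Acceptance rates are averaged per temperature and split
into a high-temperature (beta < 0.5) and low-temperature (beta >= 0.5) band.
Royston's multivariate extension of the Shapiro-Wilk test checks whether a
posterior sample is plausibly Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ais import AnnealingSchedule


@dataclass(frozen=True)
class WeightSummary:
    entropy_bits: float
    I_q: int


@dataclass(frozen=True)
class AcceptanceSummary:
    a_j: np.ndarray   # mean acceptance per temperature
    a_high: float     # mean over temperatures with beta < 0.5
    a_low: float      # mean over temperatures with beta >= 0.5


@dataclass(frozen=True)
class RoystonResult:
    statistic: float  # H, approximately chi-squared
    dof: float        # equivalent degrees of freedom e
    pvalue: float


def _check_normalized(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-8 or np.any(q < 0):
        raise ValueError("weights must be normalised (non-negative, sum to 1)")
    return q


def weight_entropy(q: np.ndarray) -> float:
    """Shannon entropy of normalised weights, in bits (0 log 0 := 0)."""
    q = _check_normalized(q)
    nz = q[q > 0]
    return float(-(nz * np.log2(nz)).sum())


def significant_count(q: np.ndarray) -> int:
    """I_q: number of normalised weights exceeding 0.01."""
    q = _check_normalized(q)
    return int((q > 0.01).sum())


def summarize_weights(q: np.ndarray) -> WeightSummary:
    return WeightSummary(weight_entropy(q), significant_count(q))


def acceptance_summary(flags: np.ndarray, schedule: AnnealingSchedule) -> AcceptanceSummary:
    """Per-temperature mean acceptance and the beta < 0.5 / beta >= 0.5 split.

    ``flags`` is (trajectories x transitions); transition k targets
    beta_{k+1}, the intermediate temperatures beta_1 .. beta_{J-1}.
    """
    flags = np.atleast_2d(np.asarray(flags, dtype=float))
    betas = schedule.betas[1:-1]
    if flags.shape[1] != betas.size:
        raise ValueError("acceptance flags do not match the schedule length")
    a_j = flags.mean(axis=0)
    high = betas < 0.5
    a_high = float(a_j[high].mean()) if high.any() else float("nan")
    a_low = float(a_j[~high].mean()) if (~high).any() else float("nan")
    return AcceptanceSummary(a_j=a_j, a_high=a_high, a_low=a_low)


def rmse(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared componentwise error between two equal-length vectors."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have equal length")
    return float(np.sqrt(np.mean((estimate - truth) ** 2)))


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 40) -> float:
    """Family-wise corrected per-test significance threshold alpha / m."""
    return alpha / n_tests


def royston_test(samples: np.ndarray) -> RoystonResult:
    """Royston's (1992) multivariate normality test.

    Each margin's Shapiro-Wilk W is mapped through Royston's normalising
    transformation to a z-score, folded to R_j = [Phi^-1(Phi(-z_j)/2)]^2, and
    the R_j are combined into H = e * mean(R_j) where the equivalent degrees
    of freedom e = d / (1 + (d-1) c_bar) shrink with the average transformed
    inter-column correlation.  H is referred to a chi-squared distribution
    with e degrees of freedom.

    Valid for sample sizes 4 <= n <= 2000 (the normalising polynomials are
    calibrated on that range); columns must be non-constant.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.ndim != 2:
        raise ValueError("samples must be an (n x d) matrix")
    n, d = x.shape
    if not 4 <= n <= 2000:
        raise ValueError("Royston's test requires 4 <= n <= 2000")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant column: Shapiro-Wilk W undefined")

    ln_n = np.log(n)
    z = np.empty(d)
    for j in range(d):
        w_j = stats.shapiro(x[:, j]).statistic
        if n <= 11:
            g = -2.273 + 0.459 * n
            m = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
            s = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
            z[j] = (-np.log(g - np.log1p(-w_j)) - m) / s
        else:
            m = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
            s = np.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
            z[j] = (np.log1p(-w_j) - m) / s

    # fold one-sided z into an equivalent chi-square(1) deviate
    r = stats.norm.ppf(np.clip(stats.norm.cdf(-z) / 2.0, 1e-300, 1.0)) ** 2

    if d == 1:
        e = 1.0
    else:
        u, l_exp = 0.715, 5.0
        v = 0.21364 + 0.015124 * ln_n**2 - 0.0018034 * ln_n**3
        corr = np.corrcoef(x, rowvar=False)
        off = corr[~np.eye(d, dtype=bool)]
        c_star = off**l_exp * (1.0 - u * (1.0 - off) ** u / v)
        c_bar = float(np.mean(c_star))
        e = d / (1.0 + (d - 1) * c_bar)

    h = float(e * np.mean(r))
    p = float(stats.chi2.sf(h, e))
    return RoystonResult(statistic=h, dof=float(e), pvalue=p)
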