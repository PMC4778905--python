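"""Two-region neural mass model of event-related cortical dynamics.

Each cortical region contains three interacting populations (pyramidal
cells, spiny stellate cells and inhibitory interneurons) in the
Jansen-Rit / DCM-for-ERP tradition.  Population firing rates pass through a
saturating sigmoid and drive postsynaptic potentials via alpha-function
synaptic kernels h(t) = (H/tau) t exp(-t/tau), each realised as a
second-order ODE

    v_ddot = (H/tau) * input - (2/tau) * v_dot - v / tau^2 .

Within- and between-region conduction delays are approximated to first
order, v_delayed = v - delta * v_dot.  The forward connection (region 1 ->
2) targets the spiny stellate population; the backward connection (2 -> 1)
targets the pyramidal and inhibitory populations.  A single region has 9
state variables (four second-order synapses plus the pyramidal potential
v_p = v_pe - v_pi); the two-region network has 18.

Ten neurophysiological quantities are estimable: extrinsic strengths a_12,
a_21, extrinsic delays delta_12, delta_21, intrinsic gains gamma_1..4 and
sigmoid parameters r_1, r_2 (shared across regions).  Each lives on an
unconstrained scale w through the positivity-preserving transform
value = default * exp(w).  Region 1 receives a Gaussian-bump subcortical
input peaking at 64 ms.  The observed channels are the two pyramidal
potentials, with known IID Gaussian noise.

Gradients and Fisher information are computed by forward sensitivity
analysis: the augmented system integrates dS/dt = (df/dx) S + df/dw jointly
with the states, and the Gauss-Newton identities turn the observed-channel
sensitivities into the likelihood gradient and Fisher matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .base import BayesianModel, Dataset, GaussianPrior

_OBS = (8, 17)  # pyramidal potential state index in each region

FULL_PARAMS = ("a12", "a21", "delta12", "delta21",
               "gamma1", "gamma2", "gamma3", "gamma4", "r1", "r2")
REDUCED_PARAMS = ("a21", "delta21",
                  "gamma1", "gamma2", "gamma3", "gamma4", "r1", "r2")


@dataclass(frozen=True)
class NMMConfig:
    """Fixed physiological constants and simulation settings.

    Synaptic magnitudes/time constants, intrinsic delays and the stimulus
    are assumed known; ``defaults`` gives the physiological value each
    estimable parameter takes at w = 0.  Values follow the Jansen-Rit /
    DCM-for-ERP literature.
    """

    H_e: float = 3.25          # excitatory synaptic magnitude (mV)
    H_i: float = 22.0          # inhibitory synaptic magnitude (mV)
    tau_e: float = 0.010       # excitatory time constant (s)
    tau_i: float = 0.020       # inhibitory time constant (s)
    delta_intra: float = 0.002  # within-region delay delta_11 = delta_22 (s)
    input_peak: float = 0.064  # stimulus peak time (s)
    input_width: float = 0.016  # stimulus Gaussian width (s)
    input_amplitude: float = 300.0  # stimulus magnitude (firing-rate units)
    t: np.ndarray = field(default_factory=lambda: np.arange(0.0, 0.3005, 0.001))
    sigma_s: tuple[float, float] = (0.01, 0.01)  # observation noise sd (mV)
    rtol: float = 1e-2
    atol: float = 1e-4
    defaults: dict = field(default_factory=lambda: {
        "a12": 16.0, "a21": 32.0,            # extrinsic strengths
        "delta12": 0.016, "delta21": 0.016,  # extrinsic delays (s)
        "gamma1": 128.0, "gamma2": 102.4,    # intrinsic gains
        "gamma3": 32.0, "gamma4": 32.0,
        "r1": 0.56, "r2": 1.0,               # sigmoid slope (1/mV), threshold (mV)
    })

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.size < 2:
            raise ValueError("time grid needs at least two points")
        for name in ("tau_e", "tau_i", "delta_intra"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "t", t)

    def stimulus(self, t) -> np.ndarray | float:
        d = (np.asarray(t) - self.input_peak) / self.input_width
        return self.input_amplitude * np.exp(-0.5 * d * d)


@dataclass
class StateTrajectory:
    """Integrated latent states, observed-channel predictions, sensitivities."""

    t: np.ndarray
    X: np.ndarray                       # (N_x, N_t)
    y_hat: np.ndarray                   # (2, N_t) pyramidal potentials
    S: Optional[np.ndarray] = None      # (N_x, N_p, N_t) forward sensitivities

    def save_sensitivities(self, path) -> None:
        """Write S as a flat text array plus a JSON shape descriptor."""
        import json
        from pathlib import Path

        if self.S is None:
            raise ValueError("trajectory carries no sensitivities")
        path = Path(path)
        np.savetxt(path, self.S.reshape(self.S.shape[0], -1))
        path.with_suffix(".json").write_text(json.dumps(
            {"shape": list(self.S.shape), "order": "state x parameter x time",
             "reshape": "C"}))

    @classmethod
    def load_sensitivities(cls, path) -> np.ndarray:
        import json
        from pathlib import Path

        path = Path(path)
        shape = json.loads(path.with_suffix(".json").read_text())["shape"]
        return np.loadtxt(path).reshape(shape)


def sigmoid_rate(x, r1, r2):
    """Population firing rate: logistic with resting output subtracted.

    s(x) = 1/(1+exp(-r1 (x - r2))) - 1/(1+exp(r1 r2)); s(0) = 0 so the
    all-zero state is a fixed point of the unforced dynamics.
    """
    return 1.0 / (1.0 + np.exp(-r1 * (np.asarray(x, dtype=float) - r2))) \
        - 1.0 / (1.0 + np.exp(r1 * r2))


def param_transform(w, config: NMMConfig, backward: bool = True) -> dict:
    """Map unconstrained w to physiological values: default * exp(w)."""
    names = FULL_PARAMS if backward else REDUCED_PARAMS
    w = np.asarray(w, dtype=float)
    if w.size != len(names):
        raise ValueError(f"expected {len(names)} parameters, got {w.size}")
    return {n: config.defaults[n] * float(np.exp(wi)) for n, wi in zip(names, w)}


def param_inverse(values: dict, config: NMMConfig, backward: bool = True) -> np.ndarray:
    """Exact inverse of :func:`param_transform` on its image (positive values)."""
    names = FULL_PARAMS if backward else REDUCED_PARAMS
    w = np.empty(len(names))
    for i, n in enumerate(names):
        v = values[n]
        if v <= 0:
            raise ValueError(f"{n} must be positive, got {v}")
        w[i] = np.log(v / config.defaults[n])
    return w


def _phys_vector(w, config: NMMConfig, backward: bool) -> dict:
    phys = dict(config.defaults)
    if not backward:
        phys["a12"] = 0.0
    phys.update(param_transform(w, config, backward))
    if not backward:
        phys["a12"] = 0.0
        phys["delta12"] = config.defaults["delta12"]
    return phys


def nmm_derivatives(x, t, phys: dict, config: NMMConfig,
                    partials: bool = False, backward: bool = True):
    """State derivative f(x, t); optionally also df/dx and df/dw.

    ``phys`` holds the physiological parameter values.  With
    ``partials=True`` returns (f, A, B) where A = df/dx (18x18) and B =
    df/dw (18 x N_p) on the unconstrained scale (chain rule through the
    exponential transform: df/dw_k = theta_k * df/dtheta_k).
    """
    x = np.asarray(x, dtype=float)
    ke, ae = config.H_e / config.tau_e, 1.0 / config.tau_e
    ki, ai = config.H_i / config.tau_i, 1.0 / config.tau_i
    di = config.delta_intra
    a12, a21 = phys["a12"], phys["a21"]
    d12, d21 = phys["delta12"], phys["delta21"]
    g1, g2, g3, g4 = phys["gamma1"], phys["gamma2"], phys["gamma3"], phys["gamma4"]
    r1, r2 = phys["r1"], phys["r2"]

    # delayed potentials: within-region (Taylor, delta_intra) and cross-region
    args = np.array([
        x[8] - di * (x[3] - x[5]),     # 0: pyramidal, region 1
        x[0] - di * x[1],              # 1: stellate,  region 1
        x[6] - di * x[7],              # 2: inhibitory, region 1
        x[17] - di * (x[12] - x[14]),  # 3: pyramidal, region 2
        x[9] - di * x[10],             # 4: stellate,  region 2
        x[15] - di * x[16],            # 5: inhibitory, region 2
        x[17] - d12 * (x[12] - x[14]),  # 6: region-2 pyramidal seen by region 1
        x[8] - d21 * (x[3] - x[5]),    # 7: region-1 pyramidal seen by region 2
    ])
    sig0 = 1.0 / (1.0 + np.exp(r1 * r2))
    lo = 1.0 / (1.0 + np.exp(-r1 * (args - r2)))
    s = lo - sig0
    sp = r1 * lo * (1.0 - lo)  # ds/darg

    u = float(config.stimulus(t))
    inp_s1 = u + g1 * s[0]
    inp_pe1 = g2 * s[1] + a12 * s[6]
    inp_i1 = g3 * s[0] + a12 * s[6]
    inp_pi1 = g4 * s[2]
    inp_s2 = g1 * s[3] + a21 * s[7]
    inp_pe2 = g2 * s[4]
    inp_i2 = g3 * s[3]
    inp_pi2 = g4 * s[5]

    f = np.empty(18)
    for o, (i_s, i_pe, i_pi, i_i) in ((0, (inp_s1, inp_pe1, inp_pi1, inp_i1)),
                                      (9, (inp_s2, inp_pe2, inp_pi2, inp_i2))):
        f[o + 0] = x[o + 1]
        f[o + 1] = ke * i_s - 2 * ae * x[o + 1] - ae * ae * x[o + 0]
        f[o + 2] = x[o + 3]
        f[o + 3] = ke * i_pe - 2 * ae * x[o + 3] - ae * ae * x[o + 2]
        f[o + 4] = x[o + 5]
        f[o + 5] = ki * i_pi - 2 * ai * x[o + 5] - ai * ai * x[o + 4]
        f[o + 6] = x[o + 7]
        f[o + 7] = ke * i_i - 2 * ae * x[o + 7] - ae * ae * x[o + 6]
        f[o + 8] = x[o + 3] - x[o + 5]

    if not partials:
        return f

    # ---- A = df/dx ------------------------------------------------------------
    A = np.zeros((18, 18))
    for o in (0, 9):
        for pair in ((0, 1), (2, 3), (4, 5), (6, 7)):
            A[o + pair[0], o + pair[1]] = 1.0
        for v_row, damp, asq in ((1, ae, ae), (3, ae, ae), (7, ae, ae)):
            A[o + v_row, o + v_row] = -2 * damp
            A[o + v_row, o + v_row - 1] = -asq * asq
        A[o + 5, o + 5] = -2 * ai
        A[o + 5, o + 4] = -ai * ai
        A[o + 8, o + 3] = 1.0
        A[o + 8, o + 5] = -1.0

    def add(row, coeff, darg):
        # darg: list of (state index, weight) of the linear delayed argument
        for idx, wgt in darg:
            A[row, idx] += coeff * wgt

    dp1 = [(8, 1.0), (3, -di), (5, di)]
    ds1 = [(0, 1.0), (1, -di)]
    di1 = [(6, 1.0), (7, -di)]
    dp2 = [(17, 1.0), (12, -di), (14, di)]
    ds2 = [(9, 1.0), (10, -di)]
    di2 = [(15, 1.0), (16, -di)]
    dpc21 = [(17, 1.0), (12, -d12), (14, d12)]  # region 2 -> 1, delay d12
    dpc12 = [(8, 1.0), (3, -d21), (5, d21)]     # region 1 -> 2, delay d21

    add(1, ke * g1 * sp[0], dp1)
    add(3, ke * g2 * sp[1], ds1)
    add(3, ke * a12 * sp[6], dpc21)
    add(5, ki * g4 * sp[2], di1)
    add(7, ke * g3 * sp[0], dp1)
    add(7, ke * a12 * sp[6], dpc21)
    add(10, ke * g1 * sp[3], dp2)
    add(10, ke * a21 * sp[7], dpc12)
    add(12, ke * g2 * sp[4], ds2)
    add(14, ki * g4 * sp[5], di2)
    add(16, ke * g3 * sp[3], dp2)

    # ---- B = df/dw (unconstrained scale) --------------------------------------
    # sigmoid partials wrt r1, r2 (shared offset term sig0 differentiates too)
    dsr1 = (args - r2) * lo * (1.0 - lo) + r2 * sig0 * (1.0 - sig0)
    dsr2 = -r1 * lo * (1.0 - lo) + r1 * sig0 * (1.0 - sig0)

    names = FULL_PARAMS if backward else REDUCED_PARAMS
    B = np.zeros((18, len(names)))
    col = {n: k for k, n in enumerate(names)}

    def put(row, name, dfdtheta):
        B[row, col[name]] += phys[name] * dfdtheta

    if backward:
        put(3, "a12", ke * s[6])
        put(7, "a12", ke * s[6])
        dd12 = -(x[12] - x[14])  # d(arg6)/d(delta12)
        put(3, "delta12", ke * a12 * sp[6] * dd12)
        put(7, "delta12", ke * a12 * sp[6] * dd12)
    put(10, "a21", ke * s[7])
    dd21 = -(x[3] - x[5])
    put(10, "delta21", ke * a21 * sp[7] * dd21)
    put(1, "gamma1", ke * s[0])
    put(10, "gamma1", ke * s[3])
    put(3, "gamma2", ke * s[1])
    put(12, "gamma2", ke * s[4])
    put(7, "gamma3", ke * s[0])
    put(16, "gamma3", ke * s[3])
    put(5, "gamma4", ki * s[2])
    put(14, "gamma4", ki * s[5])
    for rname, dsr in (("r1", dsr1), ("r2", dsr2)):
        put(1, rname, ke * g1 * dsr[0])
        put(3, rname, ke * (g2 * dsr[1] + a12 * dsr[6]))
        put(5, rname, ki * g4 * dsr[2])
        put(7, rname, ke * (g3 * dsr[0] + a12 * dsr[6]))
        put(10, rname, ke * (g1 * dsr[3] + a21 * dsr[7]))
        put(12, rname, ke * g2 * dsr[4])
        put(14, rname, ki * g4 * dsr[5])
        put(16, rname, ke * g3 * dsr[3])
    return f, A, B


def integrate_nmm(w, config: NMMConfig, backward: bool = True,
                  sensitivities: bool = False,
                  rtol: Optional[float] = None,
                  atol: Optional[float] = None) -> Optional[StateTrajectory]:
    """Stiff BDF integration from rest; returns None on solver failure.

    With ``sensitivities=True`` the augmented system (states plus the
    N_x x N_p sensitivity matrix) is integrated jointly.  The supplied
    Jacobian is block-diagonal in df/dx — exact for the states, approximate
    for the sensitivity block — which only affects the implicit solver's
    Newton iterations, not the error-controlled result.
    """
    rtol = config.rtol if rtol is None else rtol
    atol = config.atol if atol is None else atol
    t = config.t
    phys = _phys_vector(w, config, backward)
    n_p = len(FULL_PARAMS if backward else REDUCED_PARAMS)

    if not sensitivities:
        def fun(tt, x):
            return nmm_derivatives(x, tt, phys, config, backward=backward)

        def jac(tt, x):
            _, A, _ = nmm_derivatives(x, tt, phys, config, partials=True,
                                      backward=backward)
            return A

        y0 = np.zeros(18)
    else:
        def fun(tt, y):
            x = y[:18]
            S = y[18:].reshape(18, n_p, order="F")
            f, A, B = nmm_derivatives(x, tt, phys, config, partials=True,
                                      backward=backward)
            return np.concatenate([f, (A @ S + B).reshape(-1, order="F")])

        def jac(tt, y):
            _, A, _ = nmm_derivatives(y[:18], tt, phys, config, partials=True,
                                      backward=backward)
            return sparse.block_diag([A] * (1 + n_p), format="csc")

        y0 = np.zeros(18 * (1 + n_p))

    with np.errstate(over="ignore", invalid="ignore"):
        try:
            sol = solve_ivp(fun, (t[0], t[-1]), y0, method="BDF", t_eval=t,
                            rtol=rtol, atol=atol, jac=jac)
        except (ValueError, FloatingPointError):
            return None
    if sol.status != 0 or not np.all(np.isfinite(sol.y)):
        return None
    X = sol.y[:18]
    traj = StateTrajectory(t=t, X=X, y_hat=X[list(_OBS)])
    if sensitivities:
        traj.S = sol.y[18:].reshape(18, n_p, t.size, order="F")
    return traj


class TwoRegionNMM(BayesianModel):
    """Bayesian two-region neural mass model with forward-sensitivity gradients.

    ``backward=False`` structurally removes the backward connection (the
    'reduced' architecture), leaving 8 free parameters.  The prior over w is
    zero-mean with diagonal covariance: 0.16 for extrinsic strengths
    (a_12, a_21 where present), 0.0625 for everything else.
    """

    def __init__(self, data: Dataset, config: Optional[NMMConfig] = None,
                 backward: bool = True, prior: Optional[GaussianPrior] = None):
        self.config = config if config is not None else NMMConfig()
        self.backward = bool(backward)
        self.param_names = FULL_PARAMS if backward else REDUCED_PARAMS
        n_p = len(self.param_names)
        if prior is None:
            var = np.array([0.16 if n in ("a12", "a21") else 0.0625
                            for n in self.param_names])
            prior = GaussianPrior(np.zeros(n_p), np.diag(1.0 / var))
        if np.atleast_2d(data.y).shape != (2, self.config.t.size):
            raise ValueError("data.y must be 2 x N_t on the configured grid")
        super().__init__(prior, data)

    # -- forward model ----------------------------------------------------------
    def simulate(self, w, sensitivities: bool = False) -> Optional[StateTrajectory]:
        return integrate_nmm(w, self.config, backward=self.backward,
                             sensitivities=sensitivities)

    def _residual_terms(self, y_hat):
        y = np.atleast_2d(self.data.y)
        sd = np.asarray(self.config.sigma_s, dtype=float)
        resid = y - y_hat
        n_t = y.shape[1]
        const = -0.5 * n_t * np.sum(np.log(2 * np.pi * sd**2))
        ll = const - 0.5 * np.sum((resid / sd[:, None]) ** 2)
        return resid, sd, float(ll)

    def log_lik(self, w) -> float:
        traj = self.simulate(w)
        if traj is None:
            return self._failed("NMM integration failed; rejecting parameter point")
        return self._residual_terms(traj.y_hat)[2]

    def lik_grad_fisher(self, w):
        traj = self.simulate(w, sensitivities=True)
        if traj is None:
            n = self.n_params
            return (self._failed("NMM sensitivity integration failed"),
                    np.zeros(n), np.zeros((n, n)))
        resid, sd, ll = self._residual_terms(traj.y_hat)
        J = traj.S[list(_OBS)]            # (2, N_p, N_t)
        prec = 1.0 / sd**2                # per-channel precision
        grad = np.einsum("ct,cpt,c->p", resid, J, prec)
        fisher = np.einsum("cpt,cqt,c->pq", J, J, prec)
        return ll, grad, 0.5 * (fisher + fisher.T)

    def grad_log_lik(self, w):
        return self.lik_grad_fisher(w)[1]

    def fisher(self, w):
        return self.lik_grad_fisher(w)[2]

    def with_config(self, **changes) -> "TwoRegionNMM":
        return TwoRegionNMM(self.data, replace(self.config, **changes),
                            backward=self.backward, prior=self.prior)
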