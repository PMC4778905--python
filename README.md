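# aislmc

Annealed importance sampling (AIS) with Fisher-preconditioned Langevin
Monte Carlo transitions, for Bayesian parameter inference and marginal
likelihood (model evidence) estimation.

The package is aimed at people fitting nonlinear dynamical models — in
particular neural mass models of effective connectivity between cortical
regions — where the standard variational-Laplace machinery assumes a
Gaussian, unimodal posterior.  AIS makes no such assumption: it returns
independent weighted posterior samples and an evidence estimate whose
quality can be diagnosed from the importance-weight distribution itself.

## Method

A run launches `I` independent annealing *trajectories*.  Each starts from
a draw of the Gaussian prior `p(w) = N(w; μ, Λ⁻¹)` and ascends an
inverse-temperature ladder `β₀ = 0 < β₁ < … < β_J = 1` (5th-order
geometric by default, `β_j = (j/J)⁵`), applying at rung `j` one
Metropolis-adjusted Langevin step that leaves the tempered density

    f_j(w) ∝ p(y|w)^{β_j} p(w)

invariant.  The proposal is the local Gauss–Newton Gaussian approximation

    C = (Λ + β F(w))⁻¹,    w* ~ N(w + h C g_β(w), C),   h = 0.5,

with `g_β` the tempered log-joint gradient and `F` the Fisher information
(for Gaussian observation models, `JᵀJ/σ²` with `J` the prediction
Jacobian; for ODE models `J` comes from forward sensitivity analysis).
Each trajectory accumulates a log importance weight

    log v = Σ_j (β_j − β_{j−1}) · log p(y | w_j),

whose average across trajectories estimates the evidence,
`log p(y) ≈ v_max + log ū`; percentile bootstrap over trajectories gives a
90% interval.  The prior arithmetic mean (PAM) and posterior harmonic mean
(PHM) estimators are the two-temperature special cases and are provided as
baselines, together with importance sampling from an arbitrary Gaussian
proposal.

Bundled models:

* **Linear regression** on a DCT basis — fully conjugate, with analytic
  posterior and evidence used as oracles throughout the test suite.
* **Squared-coefficient regression** (`β_i = w_i²`) — a deliberately
  multimodal posterior with 2^p symmetric modes.
* **Approach-to-limit** voltage curve `y(t) = −60 + V_a(1 − e^{−t/τ})`
  with log-scale parameters.
* **Two-region neural mass model** — Jansen–Rit-style populations
  (pyramidal, spiny stellate, inhibitory) per region, alpha-kernel
  synapses, first-order delay approximation, forward connection to the
  granular layer and backward connection to pyramidal/inhibitory
  populations; 10 estimable log-transformed physiological parameters;
  gradients and Fisher information by forward sensitivities integrated
  with the states under a stiff BDF scheme.

Diagnostics include the weight entropy (bits), the count `I_q` of
significant weights, per-temperature acceptance profiles, Royston's
multivariate normality test on the posterior samples, and parameter-recovery
RMSE.

## Worked example

```python
from aislmc import LinearRegressionModel, gen_linear

data = gen_linear(seed=0)            # 7 DCT regressors, N=20, sigma=0.2
model = LinearRegressionModel(data)
res = model.fit(n_temps=512, n_traj=32, seed=0)
print(res.summary())
print("analytic:", round(model.analytic_log_evidence(), 3))
```

prints

```
Annealed Importance Sampling results
====================================================
trajectories (I)        32
temperatures (J)        512 (order-5 schedule)
log evidence               -11.531
  bootstrap 90% CI      [-11.814, -11.300]
weight entropy (bits)         4.56
significant weights I_q         27
acceptance a_high/a_low 0.75 / 0.76
----------------------------------------------------
parameter   post. mean   post. sd
w1               0.223      0.180
w2              -0.760      0.149
...
analytic: -11.419
```

The AIS evidence (−11.53) sits within a tenth of a nat of the exact
conjugate value (−11.42) and inside its own bootstrap interval; the weight
entropy is close to its 5-bit maximum and 27 of 32 trajectories carry
significant weight, indicating a healthy annealing run.  The posterior
means track the generating coefficients (e.g. `w7`: 4.139 vs truth 4.124).

The same workflow is available from the shell:

```sh
aislmc generate --model nmm --seed 1 --out data/nmm.csv
aislmc fit --model nmm --data data/nmm.csv --out runs/full -J 128 -I 8 --seed 1
aislmc fit --model nmm --data data/nmm.csv --out runs/red  -J 128 -I 8 --seed 2 --reduced
aislmc compare runs/full runs/red
```

`compare` reports the log Bayes factor (with bootstrap interval) between
the full two-region model and the reduced one lacking the backward
connection.

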