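# thermokin

Thermodynamically consistent Bayesian calibration of closed mass-action
biochemical reaction systems.

## The problem

Given a reaction network with known stoichiometry, rate-constant
estimation from noisy concentration time series is a standard model
calibration task — but most calibration methods ignore the constraints
thermodynamics places on the rate constants.  In a closed system the
product of equilibrium constants around every stoichiometric cycle must
equal one (the **Wegscheider conditions**): for every vector r in the
null space of the stoichiometry matrix S,

    prod_m (k_2m-1 / k_2m)^{r_m} = 1 .

Estimates that violate these conditions describe dynamics that cannot
occur in nature (a cycle with perpetual net flux at equilibrium).
`thermokin` is for modellers in systems biology and chemical kinetics
who want rate-constant posteriors that are *guaranteed* feasible, plus
principled answers to design questions — how many time points, which
species to perturb, replication versus perturbation.

## The method

The 2M log-rate constants kappa split into M + M1 free coordinates
(M1 = rank S) and M − M1 dependent ones with kappa_d = W kappa_f.  All
inference runs on the free coordinates, so every evaluated parameter set
lies on the feasible manifold by construction.  The unnormalized
posterior combines three analytically marginalized ingredients,

    p(kappa | y)  ∝  omega(kappa) · psi(kappa, ybar)^(−alpha) · phi(kappa, y)^(−beta),

where omega is an Arrhenius-derived prior on forward log-rates
(exponentially modified Gaussian: kappa0 + N(0, lambda²) − Exp(tau)),
psi is a steady-state-data-derived prior on the log-equilibrium
constants built from the SVD pseudo-inverse of SᵀS, phi is the
sum-of-squares statistic of the transient log-residuals (each
evaluation integrates the kinetic ODEs for the unperturbed system and
each perturbation), and beta = alpha + N(P+1)Q/2.  The mode is found by
a **MEM** schedule — SPSA stochastic ascent from the prior mode,
random-walk Metropolis for the posterior mean and covariance, SPSA
again from the mean — reporting the best point seen anywhere.
Accuracy is summarized by per-parameter posterior RMSEs, the
D-criterion ln det(V)/(M+M1), and median/maximum normalized integrated
dynamics errors against a known truth.  See `docs/methods.md` for the
full treatment.

## Worked example

Calibrate the packaged 3-reaction chain A⇄B⇄C⇄D from synthetic data
(σ = 0.3 multiplicative noise, Q = 6 log-spaced times, perturbations
A ×100 up and D ×100 down):

```python
import numpy as np, thermokin as tk

net, _, kappa_true, design = tk.fixture_network("chain3")
scheme = tk.SamplingScheme(kind="logarithmic", Q=6, t_max=design.t_max)
data = tk.generate_measurements(net, kappa_true, design,
                                tk.NoiseModel(sigma=0.3), 11, scheme=scheme)
ctx = tk.build_context(net, data.design, data,
                       tk.VarianceHyperparams(alpha=3, b=1),
                       tk.elicit_arrhenius_hyperparams(0.01, 100.0))
res = tk.mem_estimate(ctx, tk.SPSAConfig(iterations=500),
                      tk.MCMCConfig(iterations=5000), seed=11)
print("true kappa_f :", np.round(ctx.decomp.extract_free(kappa_true), 3))
print("mode kappa_f :", np.round(res.mode_f, 3))
print("RMSE         :", np.round(tk.posterior_rmse(res.samples, res.mode_f), 3))
print("D            :", round(tk.d_criterion(res.covariance, ctx.decomp.n_free), 4))
med, mx = tk.median_max_abs_error(net, kappa_true,
                                  tk.KineticParameters(res.kappa_hat), data.design)
print("med/max AE   :", f"{med:.3f}", f"{mx:.3f}")
```

prints

```
true kappa_f : [ 1.099  0.     0.693  0.405 -0.223  0.182]
mode kappa_f : [ 1.015 -0.124  0.934  0.919 -0.378 -0.016]
RMSE         : [0.141 0.231 0.342 0.453 0.239 0.366]
D            : -3.4451
med/max AE   : 0.094 0.142
```

Each coordinate of the mode lands within about one posterior SD of its
generating value; the D-criterion of −3.45 summarizes the overall
posterior concentration, and the integrated dynamics errors say that
half of the (species, perturbation) trajectories are reproduced to
better than 9.4% and the worst to 14.2%.  The assembled estimate
satisfies the Wegscheider residual test to 1e−12 by construction, as
does every point the sampler ever touched.

The same pipeline is available from the shell:

```
thermokin generate-data model.json -o meas.csv --sigma 0.3 -Q 6 --seed 1
thermokin calibrate model.json meas.csv -o fit.json -I 500 -L 5000 --seed 1
thermokin project published_model.json -o feasible_model.json
```

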