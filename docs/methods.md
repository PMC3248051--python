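# Methods

## The model

`thermokin` calibrates a *closed* biochemical reaction system: N species
X_1..X_N coupled by M reversible reactions

    sum_n nu_nm X_n  <-->  sum_n nu'_nm X_n,        m = 1..M,

with strictly positive forward/reverse rate constants k_{2m-1}, k_{2m}
(an irreversible reaction is thermodynamically impossible in a closed
system).  Concentrations follow deterministic mass-action kinetics,

    dx_n/dt = sum_m s_nm rho_m(x),
    rho_m(x) = k_{2m-1} prod_i x_i^{nu_im} - k_{2m} prod_i x_i^{nu'_im},

with S = (s_nm) = nu' - nu the net stoichiometry matrix.  Estimation
works on the natural-log scale, kappa_{2m-1} = ln k_{2m-1} etc., which
compresses the dynamic range and makes the multiplicative measurement
errors additive.

Data come from perturbation experiments: besides the unperturbed run
(label p = 0), the initial concentration of one species at a time is
shifted by pi_p >= -c_p (injection/transfection up, RNAi down).  Each
run is sampled at Q transient times plus one near-steady-state time, and
log-concentrations are observed with error:
y_n^(p)(t_q) = ln x_n^(p)(t_q) + eta_n^(p)(t_q).

## Thermodynamic feasibility

At steady state every net flux of a closed system vanishes (detailed
balance).  This forces the log-equilibrium constants
z_m = kappa_{2m-1} - kappa_{2m} to satisfy r^T z = 0 for every r in
null(S) — the Wegscheider conditions: the product of equilibrium
constants around any stoichiometric cycle equals one.  With
M1 = rank(S), the feasible set is an (M + M1)-dimensional hyperplane in
the 2M-dimensional log-rate space.  The package decomposes kappa into
free coordinates (all M forward rates plus M1 reverse rates) and
M - M1 dependent reverse rates, kappa_d = W kappa_f.  Which reverse
rates become dependent is chosen by column-pivoted QR of the constraint
matrix restricted to reverse coordinates — the best-conditioned solve —
and the choice is reported in serialized output, since any valid pivot
gives the same manifold but different bookkeeping.

Literature rate compilations rarely satisfy the conditions, so
`project_to_feasible` computes the unweighted Euclidean least-squares
projection in log-rate space onto the hyperplane (closed form via the
constraint normal equations).  The projection is idempotent and fixes
feasible points.

## Priors

* **Error variance**: inverse-gamma with shape alpha and scale b (the
  conjugate prior for the variance of additive Gaussian errors);
  defaults alpha = 3, b = 1 give prior mean E[sigma^2] = 0.5 and
  variance 0.25.
* **Forward log-rates**: from the Arrhenius law with a log-normal
  prefactor perturbation g ~ N(0, lambda^2) and an exponential
  activation-energy excess with mean k_B T* (tau = T*/T > 1), each
  forward log-rate is kappa0 + g - Exp(tau): a left-skewed
  exponentially-modified Gaussian with mean kappa0 - tau and variance
  lambda^2 + tau^2.  The density involves erfc times a growing
  exponential; it is evaluated through the normal log-CDF
  (`scipy.special.log_ndtr`) so that arguments out to |u| ~ 40 neither
  overflow nor underflow.
* **Log-equilibrium constants**: steady-state measurements give the
  unbiased estimate y_tilde_m = (1/(P+1)) sum_p sum_n s_nm ybar_n^(p)
  of z_m; marginalizing its error variance against the inverse-gamma
  prior yields a Student-type density in the quadratic form
  (z - y_tilde)^T theta (z - y_tilde), where theta is the rank-truncated
  SVD pseudo-inverse of H = S^T S (H is singular whenever S has a null
  space, so the truncation is essential; null directions of theta leave
  the prior flat, as they should — steady states carry no information
  about them).

Hyperparameter elicitation maps a plausible rate range (k_low, k_high)
to (kappa0, tau, lambda): prior mean at the log-midpoint, prior sd at a
quarter of the log-range, and the shape ratio lambda/tau fixed at 0.390
(the ratio of the reference hyperparameter set); tau is floored just
above 1 if the range is very narrow.  The toy fixtures in this package
use the range k in [0.01, 100] (prior mean 0, sd 2.30), which brackets
their O(1) rates; a prior elicited for a different rate scale would
dominate the likelihood and bias the mode, which is a property of the
method, not an artifact.

## Posterior and its feasible marginal

Integrating out sigma^2 and the Arrhenius randomness gives the
unnormalized posterior

    p(kappa | y) ∝ omega(kappa) * psi(kappa, y)^-alpha * phi(kappa, y)^-beta,

with phi = 2b + sum of squared transient log-residuals (one ODE solve
per perturbation), psi = 2b/(P+1) + the equilibrium quadratic form,
omega the product of Arrhenius factors, and beta = alpha + N(P+1)Q/2.
Everything is evaluated in log space (beta easily exceeds 100, so
phi^beta overflows as written).  The transient and steady acquisitions
must be independent — the steady block builds the prior, the transient
block the likelihood.

Feasibility enters by the encompassing-prior construction: the prior is
multiplied by a Dirac density on kappa_d = W kappa_f, and the dependent
coordinates are integrated out.  Operationally the marginal posterior
over kappa_f is just the unconstrained posterior evaluated at the
assembled kappa — the delta is realized by parameterizing on the
manifold, never by evaluating it.  Every evaluation asserts the
Wegscheider residuals are below 1e-12; a violation raises immediately.

Failed integrations (stiff blow-ups at extreme kappa during sampling)
return -inf, i.e. the proposal is rejected rather than aborting the
run; the failure count is kept on the evaluation context.

## The MEM estimator

The mode of the (generally non-concave) marginal log-posterior is
estimated by a maximization-expectation-maximization schedule:

1. SPSA from the prior mode (forward coordinates at the numeric mode of
   the Arrhenius prior; z initialized from y_tilde with its null-space
   component projected out).
2. Random-walk Metropolis from the SPSA iterate: isotropic Gaussian
   proposals, scale adapted multiplicatively every 50 iterations during
   the 20% burn-in toward 30% acceptance and frozen afterwards
   (preserving detailed balance of the retained chain).
3. SPSA again from the posterior mean.

The reported mode is the argmax over *all* points evaluated in all
stages (probe points included).  SPSA uses the standard gain exponents
(0.602, 0.101), A = 0.1 I, c = 0.1, and auto-scales the step gain so
the first step is about 0.1 per coordinate; steps are capped at unit
max-norm to guard against rare divergent excursions.  Each stage draws
from a separately spawned, named seed stream, making the whole run a
pure function of (data, config, seed).

The posterior covariance V is the second-moment matrix of the
post-burn-in samples about the *mode* (not the mean) — this is the
matrix whose diagonal gives the per-parameter RMSE and whose average
log-eigenvalue is the D-criterion, D = ln det(V)/(M + M1).  RMSEs are
reported for free parameters only; dependent log-rates are deterministic
functions of the free set and get a dash in tables.

## Accuracy criteria

When the generating system is known, dynamics closeness is measured per
(species, perturbation) pair as the time integral of |x_hat - x|
divided by the integral of x, both by composite trapezoid on a 201-point
grid mixing linear and geometric spacing over (0, t_max] (the geometric
half resolves fast transients).  The median and maximum over pairs are
reported; by construction half the normalized errors lie below the
median.  The D-criterion percent-change between successive designs is
reported as (D_prev - D_curr)/|D_prev| * 100, positive = improvement.

## Synthetic-data generator

`generate_measurements` emulates the assumed acquisition: simulate all
P+1 runs (LSODA with analytic Jacobian; generation uses rtol 1e-8 /
atol 1e-10, posterior evaluation rtol 1e-6 / atol 1e-9), take
log-concentrations at the scheme's times, and add errors from one of
three families — i.i.d. Gaussian (the model's assumption), i.i.d.
uniform on [-sqrt(3) sigma, sqrt(3) sigma], or stationary Gaussian with
covariance sigma^2 exp(-|t1 - t2|) (timescale one time unit; one
multivariate draw per series).  Transient and steady errors come from
independently spawned streams.  The generator refuses an infeasible
truth unless explicitly overridden for robustness studies.

What it does *not* emulate: species-dependent error variances, missing
or partially observed species, ratio-type (reference-normalized)
measurements, estimation error in the initial concentrations or
perturbations, and open-system mass exchange.  Passing tests therefore
demonstrate correctness of the method under its own stated assumptions,
not robustness to these real-data complications.

## Packaged fixtures and problem sizes

* `two_state` (A<->B, k = (2,1)): analytically solvable; 2 free
  parameters, used for grid-quadrature cross-checks.
* `triangle` (A<->B<->C<->A): the minimal cycle, one Wegscheider
  constraint; its published rate set deliberately violates the loop
  condition (z-sum 0.3) and projects to the uniform 0.05 vector.
* `dimerization` (2A<->B): nonlinear kinetics with an analytic steady
  state.
* `chain3` (A<->B<->C<->D): the calibration workhorse — 6 free
  parameters, no cycle constraints, perturbations A x100 up (injection)
  and D x100 down (knockdown), a realistic up/down x100
  perturbation design (molecular injection, RNAi-style knockdown).  Without the knockdown the C<->D end of the chain is
  weakly identified and the posterior mode itself (verified with a
  derivative-free optimizer oracle) sits ~0.02 from the truth even with
  noiseless data.
* `egf_erk_subset`: a transcription slot for the N = 13, M = 9
  reversible mass-action subset of the EGF/ERK cascade; raises a clear
  error until its supplementary reaction list and rate table are
  transcribed into the fixture store.

Default study conditions follow the reference setup: sigma = 0.3
i.i.d. Gaussian errors, Q = 6 logarithmically spaced times, steady-state
sample at t_max, alpha = 3, b = 1.  The packaged test suite and the
acceptance script run the estimator at I = 500 SPSA iterations and
L = 5000 MCMC iterations on the toys (with I = 1000 for the zero-noise
recovery run and lighter I = 150 / L = 1200 inside the design sweep);
these sizes were chosen as the smallest at which the Monte Carlo
summaries are stable on the 6-parameter chain.

## Numerical choices and limitations

* Rank decisions use a 1e-10 relative singular-value threshold; S is an
  integer matrix, so rank is unambiguous in practice.
* Steady states are found by integrating on doubling horizons from
  t_max until max_m |rho_m| < 1e-9 times the total initial
  concentration.
* The integrator clips marginally negative excursions to zero before
  they enter the mass-action powers; a non-positive concentration at a
  *sampled* time is an error (log-measurements are undefined there).
* The logarithmic scheme anchors its first sample at t_max/100 unless
  given explicitly; the steady-state sample sits at t_max, which is
  adequate for the fixtures (their slowest relaxation times are well
  inside the window) but should be checked for stiff user models.
* The quadrature grid (201 points) limits the resolution of the
  integrated-error criteria for dynamics faster than ~t_max/1000.
* SPSA is a stochastic optimizer: the mode estimate carries Monte Carlo
  error of the same order as its gain schedule's final step size; the
  argmax-over-all-iterates rule makes it conservative but not exact.
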