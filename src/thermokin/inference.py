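"""Posterior-mode estimation by the sequential MEM schedule.

The marginal log-posterior over the free log-rates is generally
non-concave, and each evaluation costs P+1 ODE solves, so gradient-based
optimizers are unattractive.  The estimator here chains three stages:

1. maximization — SPSA (simultaneous perturbation stochastic
   approximation), a gradient-free stochastic ascent using two objective
   evaluations per iteration along a random +-1 direction, started from
   the prior mode;
2. expectation — random-walk Metropolis MCMC started from the SPSA
   iterate, giving posterior samples, their mean, and a covariance
   estimate;
3. maximization — a second SPSA run started from the posterior mean.

The reported mode is the argmax of the log-posterior over *every* point
evaluated in all three stages; the covariance V-hat is the second-moment
matrix of the post-burn-in samples about that mode (the form the RMSE and
D-criterion definitions use).  The whole schedule is a pure function of
(data, config, seed): SPSA-1, MCMC and SPSA-2 draw from separately
spawned named streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .posterior import PosteriorContext, log_marginal_posterior
from .priors import forward_rate_prior_mode
from .thermodynamics import assemble_full

__all__ = [
    "SPSAConfig",
    "MCMCConfig",
    "MEMResult",
    "prior_mode_init",
    "spsa_maximize",
    "mcmc_sample",
    "mem_estimate",
]


@dataclass(frozen=True)
class SPSAConfig:
    """SPSA gain schedule a_k = a/(k+1+A)^alpha_gain, c_k = c/(k+1)^gamma_gain.

    The standard gain exponents (0.602, 0.101) are the defaults.  When
    ``a`` is None it is auto-scaled so the first step has magnitude about
    0.1 per coordinate, which guards against divergence on steep
    objectives.
    """

    iterations: int = 500
    a: float | None = None
    A: float | None = None  # defaults to 0.1 * iterations
    alpha_gain: float = 0.602
    c: float = 0.1
    gamma_gain: float = 0.101
    first_step: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.c <= 0 or (self.a is not None and self.a < 0):
            raise ValueError("gains must be positive (a may be 0 for probe-only runs)")
        if not 0.5 < self.alpha_gain <= 1.0:
            raise ValueError("alpha_gain must lie in (0.5, 1]")
        if not 0.0 < self.gamma_gain < self.alpha_gain:
            raise ValueError("gamma_gain must lie in (0, alpha_gain)")

    @property
    def stability(self) -> float:
        return 0.1 * self.iterations if self.A is None else self.A


@dataclass(frozen=True)
class MCMCConfig:
    """Random-walk Metropolis settings.

    Isotropic Gaussian proposals; the scale adapts every
    ``adapt_window`` iterations during burn-in toward the target
    acceptance rate and is frozen afterwards (preserving detailed
    balance for the retained samples).
    """

    iterations: int = 5000
    burnin_fraction: float = 0.2
    initial_scale: float = 0.1
    adapt_window: int = 50
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burn-in fraction must lie in [0, 1)")
        if self.initial_scale <= 0:
            raise ValueError("initial proposal scale must be positive")


@dataclass
class MEMResult:
    """Output of one MEM run."""

    mode_f: np.ndarray  # free-coordinate posterior mode estimate
    mean_f: np.ndarray  # MCMC posterior mean of the free coordinates
    kappa_hat: np.ndarray  # assembled full 2M log-rate vector (feasible)
    samples: np.ndarray  # post-burn-in MCMC samples, L_post x (M+M1)
    covariance: np.ndarray  # second moment about the mode
    best_log_posterior: float
    acceptance_rate: float
    spsa_traces: tuple[np.ndarray, np.ndarray]  # best-value traces of both runs
    mcmc_logpost_trace: np.ndarray
    seeds: dict = field(default_factory=dict)


def prior_mode_init(ctx: PosteriorContext) -> np.ndarray:
    """Free-coordinate start point built from the prior mode.

    Forward coordinates take the numeric mode of the Arrhenius prior.
    The equilibrium-constant vector is initialized from y_tilde with its
    null-space component (unidentifiable from steady-state data, and
    infeasible) projected out; free reverse coordinates follow as
    kappa_{2m-1} - z_m.
    """
    M = ctx.net.n_reactions
    kappa = np.empty(2 * M)
    for m in range(M):
        kappa[2 * m] = forward_rate_prior_mode(ctx.arr_hyper, m)
    z0 = ctx.eqstats.y_tilde.copy()
    R = ctx.decomp.null_basis
    if R.size:
        z0 -= R @ (R.T @ z0)
    kappa[1::2] = kappa[0::2] - z0
    return kappa[ctx.decomp.free_indices]


def spsa_maximize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cfg: SPSAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximize a noisy/expensive objective by SPSA.

    Returns the best point over all evaluated points (probe points
    included, final iterate not privileged), its objective value, and
    the running-best trace.
    """
    x = np.asarray(x0, dtype=float).copy()
    f0 = objective(x)
    if not np.isfinite(f0):
        raise ValueError("objective must be finite at the SPSA start point")
    best_x, best_f = x.copy(), f0
    A = cfg.stability

    # auto-scale a from the first-probe gradient magnitude
    if cfg.a is None:
        delta = rng.choice((-1.0, 1.0), size=x.size)
        c0 = cfg.c
        fp, fm = objective(x + c0 * delta), objective(x - c0 * delta)
        for f_probe, x_probe in ((fp, x + c0 * delta), (fm, x - c0 * delta)):
            if f_probe > best_f:
                best_x, best_f = x_probe.copy(), f_probe
        g0 = abs(fp - fm) / (2.0 * c0) if np.isfinite(fp) and np.isfinite(fm) else 0.0
        a = cfg.first_step * (1.0 + A) ** cfg.alpha_gain / max(g0, 1e-12)
    else:
        a = cfg.a

    trace = np.empty(cfg.iterations)
    for k in range(cfg.iterations):
        ak = a / (k + 1.0 + A) ** cfg.alpha_gain
        ck = cfg.c / (k + 1.0) ** cfg.gamma_gain
        delta = rng.choice((-1.0, 1.0), size=x.size)
        fp = objective(x + ck * delta)
        fm = objective(x - ck * delta)
        if fp > best_f:
            best_x, best_f = x + ck * delta, fp
        if fm > best_f:
            best_x, best_f = x - ck * delta, fm
        if np.isfinite(fp) and np.isfinite(fm):
            ghat = (fp - fm) / (2.0 * ck) * delta  # delta_i^{-1} = delta_i for +-1
            step = ak * ghat
            # cap the step to avoid rare divergent excursions
            nrm = float(np.max(np.abs(step)))
            if nrm > 1.0:
                step *= 1.0 / nrm
            x_new = x + step
            f_new = objective(x_new)
            if np.isfinite(f_new):
                x = x_new
                if f_new > best_f:
                    best_x, best_f = x_new.copy(), f_new
        trace[k] = best_f
    return best_x, best_f, trace


def mcmc_sample(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    cfg: MCMCConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, tuple[np.ndarray, float], np.ndarray]:
    """Random-walk Metropolis targeting exp(objective).

    Returns (post-burn-in samples, their mean, post-adaptation acceptance
    rate, (best point, best value), log-posterior trace).
    """
    x = np.asarray(x0, dtype=float).copy()
    f = objective(x)
    if not np.isfinite(f):
        raise ValueError("objective must be finite at the MCMC start point")
    best_x, best_f = x.copy(), f
    L = cfg.iterations
    burn = int(round(cfg.burnin_fraction * L))
    scale = cfg.initial_scale
    samples = np.empty((L, x.size))
    logpost = np.empty(L)
    accepted_window = 0
    accepted_post = 0
    for i in range(L):
        prop = x + scale * rng.standard_normal(x.size)
        fp = objective(prop)
        if np.log(rng.uniform()) < fp - f:
            x, f = prop, fp
            accepted_window += 1
            if i >= burn:
                accepted_post += 1
            if fp > best_f:
                best_x, best_f = prop.copy(), fp
        samples[i] = x
        logpost[i] = f
        if i < burn and (i + 1) % cfg.adapt_window == 0:
            rate = accepted_window / cfg.adapt_window
            # Robbins-Monro-style multiplicative update toward the target
            scale *= float(np.exp(rate - cfg.target_acceptance))
            accepted_window = 0
        elif (i + 1) == burn:
            accepted_window = 0
    post = samples[burn:]
    n_post = max(L - burn, 1)
    acc_rate = accepted_post / n_post
    return post, post.mean(axis=0), acc_rate, (best_x, best_f), logpost


def mem_estimate(
    ctx: PosteriorContext,
    spsa_cfg: SPSAConfig | None = None,
    mcmc_cfg: MCMCConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> MEMResult:
    """Run the full maximization-expectation-maximization schedule."""
    spsa_cfg = spsa_cfg or SPSAConfig()
    mcmc_cfg = mcmc_cfg or MCMCConfig()
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    ss_spsa1, ss_mcmc, ss_spsa2 = ss.spawn(3)

    def objective(x: np.ndarray) -> float:
        return log_marginal_posterior(x, ctx)

    x0 = prior_mode_init(ctx)
    if not np.isfinite(objective(x0)):
        raise RuntimeError("log posterior is not finite at the prior-mode start")

    x1, f1, trace1 = spsa_maximize(objective, x0, spsa_cfg, np.random.default_rng(ss_spsa1))
    samples, mean_f, acc, (xb, fb), lp_trace = mcmc_sample(
        objective, x1, mcmc_cfg, np.random.default_rng(ss_mcmc)
    )
    x2, f2, trace2 = spsa_maximize(objective, mean_f, spsa_cfg, np.random.default_rng(ss_spsa2))

    candidates = [(f1, x1), (fb, xb), (f2, x2)]
    fm = objective(mean_f)
    if np.isfinite(fm):
        candidates.append((fm, mean_f))
    best_f, best_x = max(candidates, key=lambda t: t[0])
    if not np.isfinite(best_f):
        raise RuntimeError("no MEM stage produced a finite posterior value")

    dev = samples - best_x
    V = dev.T @ dev / samples.shape[0]
    kappa_hat = assemble_full(best_x, ctx.decomp).kappa
    return MEMResult(
        mode_f=best_x,
        mean_f=mean_f,
        kappa_hat=kappa_hat,
        samples=samples,
        covariance=V,
        best_log_posterior=float(best_f),
        acceptance_rate=acc,
        spsa_traces=(trace1, trace2),
        mcmc_logpost_trace=lp_trace,
        seeds={"spsa1": ss_spsa1.entropy, "mcmc": ss_mcmc.entropy, "spsa2": ss_spsa2.entropy},
    )
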