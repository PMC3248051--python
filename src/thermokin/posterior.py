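"""The effective posterior over log-rate constants and its feasible marginal.

Integrating the error variance (inverse-gamma prior) and the prefactor /
activation-energy randomness out of the hierarchical model yields an
analytic unnormalized posterior over the 2M log-rate constants:

    p(kappa | y)  ∝  omega(kappa) / [ psi(kappa, y)^alpha * phi(kappa, y)^beta ]

with

    omega(kappa) = prod_m erfc[(lambda/tau + (kappa_{2m-1}-kappa0)/lambda)/sqrt(2)]
                   * e^{kappa_{2m-1}/tau}                      (Arrhenius prior)
    psi(kappa,y) = 2b/(P+1) + (z - y_tilde)^T theta (z - y_tilde)
                                              (steady-state equilibrium prior)
    phi(kappa,y) = 2b + sum_{n,p,q} [y_n^(p)(t_q) - ln x_n^(p)(t_q; kappa)]^2
                                                        (effective likelihood)
    beta = alpha + N (P+1) Q / 2.

Thermodynamic feasibility is imposed through the encompassing-prior
construction: the Dirac constraint kappa_d = W kappa_f is realized by
parameterizing on the feasible manifold, so the marginal posterior over the
free coordinates is simply the unconstrained posterior evaluated at the
assembled kappa.  Every evaluation asserts the Wegscheider residuals
vanish to 1e-12 — the defining guarantee of the method.

Everything is computed in log space: beta routinely exceeds 100, so
phi^beta would overflow, and the erfc prefactor in omega would overflow on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import (
    ArrheniusHyperparams,
    EquilibriumPriorStats,
    VarianceHyperparams,
    _log_erfc,
    equilibrium_stats,
)
from .reaction_model import (
    ExperimentDesign,
    KineticParameters,
    ReactionNetwork,
    SimulationError,
    simulate,
)
from .thermodynamics import (
    ThermoDecomposition,
    assemble_full,
    decompose,
    wegscheider_residuals,
)

__all__ = [
    "MeasurementSet",
    "PosteriorContext",
    "build_context",
    "phi",
    "psi",
    "omega",
    "log_posterior",
    "log_marginal_posterior",
]

FEASIBILITY_TOL = 1e-12


@dataclass(frozen=True)
class MeasurementSet:
    """Complete transient and steady-state log-measurements of one study.

    ``transient`` is N x (P+1) x Q, ``steady`` is N x (P+1); perturbation
    columns are ordered as ``design.labels`` (unperturbed first).  The
    transient and steady acquisitions must carry independent errors — the
    steady block feeds the equilibrium prior, the transient block the
    likelihood, and the posterior factorization relies on their
    independence.
    """

    transient: np.ndarray
    steady: np.ndarray
    design: ExperimentDesign
    transient_times: np.ndarray
    steady_time: float

    def __post_init__(self) -> None:
        y = np.asarray(self.transient, dtype=float)
        ybar = np.asarray(self.steady, dtype=float)
        tq = np.asarray(self.transient_times, dtype=float)
        object.__setattr__(self, "transient", y)
        object.__setattr__(self, "steady", ybar)
        object.__setattr__(self, "transient_times", tq)
        n_exp = len(self.design.labels)
        if y.ndim != 3 or y.shape[1] != n_exp or y.shape[2] != tq.size:
            raise ValueError("transient block must be N x (P+1) x Q")
        if ybar.shape != (y.shape[0], n_exp):
            raise ValueError("steady block must be N x (P+1)")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(ybar))):
            raise ValueError("measurement set is incomplete (non-finite entries)")
        if tq.size and not self.steady_time > tq[-1]:
            raise ValueError("steady-state time must follow the transient times")

    @property
    def n_species(self) -> int:
        return self.transient.shape[0]

    @property
    def Q(self) -> int:
        return self.transient.shape[2]

    @property
    def P(self) -> int:
        return self.transient.shape[1] - 1


@dataclass
class PosteriorContext:
    """Everything needed to evaluate the posterior at a kappa."""

    net: ReactionNetwork
    design: ExperimentDesign
    data: MeasurementSet
    decomp: ThermoDecomposition
    var_hyper: VarianceHyperparams
    arr_hyper: ArrheniusHyperparams
    eqstats: EquilibriumPriorStats
    rtol: float = 1e-6
    atol: float = 1e-9
    n_failures: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def beta(self) -> float:
        """Likelihood exponent beta = alpha + N(P+1)Q/2."""
        n, p, q = self.data.n_species, self.data.P, self.data.Q
        return self.var_hyper.alpha + n * (p + 1) * q / 2.0


def build_context(
    net: ReactionNetwork,
    design: ExperimentDesign,
    data: MeasurementSet,
    var_hyper: VarianceHyperparams,
    arr_hyper: ArrheniusHyperparams,
    decomp: ThermoDecomposition | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PosteriorContext:
    """Assemble a posterior context; derives the equilibrium prior from data."""
    if decomp is None:
        decomp = decompose(net)
    eqstats = equilibrium_stats(data.steady, net, var_hyper)
    return PosteriorContext(
        net=net,
        design=design,
        data=data,
        decomp=decomp,
        var_hyper=var_hyper,
        arr_hyper=arr_hyper,
        eqstats=eqstats,
        rtol=rtol,
        atol=atol,
    )


def _log_concentrations(kappa: KineticParameters, ctx: PosteriorContext) -> np.ndarray:
    """ln x_n^(p)(t_q) for all species/perturbations/times (N x (P+1) x Q).

    One ODE solve per perturbation label; the most recent few evaluations
    are cached so phi and downstream metrics can share solves.
    """
    key = kappa.kappa.tobytes()
    hit = ctx._cache.get(key)
    if hit is not None:
        return hit
    tq = ctx.data.transient_times
    out = np.empty((ctx.data.n_species, len(ctx.design.labels), tq.size))
    for j, p in enumerate(ctx.design.labels):
        traj = simulate(
            ctx.net, kappa, ctx.design, p, eval_times=tq, rtol=ctx.rtol, atol=ctx.atol
        )
        x = traj.concentrations  # Q x N
        if np.any(x <= 0.0) or not np.all(np.isfinite(x)):
            raise SimulationError(
                f"non-positive concentration at sampled times for perturbation {p}"
            )
        out[:, j, :] = np.log(x).T
    if len(ctx._cache) >= 8:
        ctx._cache.clear()
    ctx._cache[key] = out
    return out


def phi(kappa: KineticParameters, ctx: PosteriorContext) -> float:
    """Effective-likelihood statistic 2b + sum of squared log residuals."""
    lnx = _log_concentrations(kappa, ctx)
    resid = ctx.data.transient - lnx
    return 2.0 * ctx.var_hyper.b + float(np.sum(resid**2))


def psi(kappa: KineticParameters, ctx: PosteriorContext) -> float:
    """Equilibrium-prior statistic 2b/(P+1) + (z-y_tilde)^T theta (z-y_tilde)."""
    st = ctx.eqstats
    d = kappa.z - st.y_tilde
    return 2.0 * st.b / (st.P + 1) + float(d @ st.theta @ d)


def omega(kappa: KineticParameters, ctx: PosteriorContext) -> float:
    """Log of the Arrhenius prior factor over all forward log-rates."""
    h = ctx.arr_hyper
    k0 = np.broadcast_to(np.asarray(h.kappa0, dtype=float), (kappa.n_reactions,))
    tau = np.broadcast_to(np.asarray(h.tau, dtype=float), k0.shape)
    lam = np.broadcast_to(np.asarray(h.lam, dtype=float), k0.shape)
    kf = kappa.forward
    u = (lam / tau + (kf - k0) / lam) / np.sqrt(2.0)
    return float(np.sum(_log_erfc(u) + kf / tau))


def log_posterior(kappa: KineticParameters, ctx: PosteriorContext) -> float:
    """Unnormalized log posterior log omega - alpha log psi - beta log phi.

    Failed integrations (stiff blow-ups at extreme kappa during sampling)
    return -inf — the point is treated as rejected rather than aborting
    the run; the failure count accumulates on the context.
    """
    try:
        lphi = np.log(phi(kappa, ctx))
    except SimulationError:
        ctx.n_failures += 1
        return -np.inf
    return (
        omega(kappa, ctx)
        - ctx.var_hyper.alpha * np.log(psi(kappa, ctx))
        - ctx.beta * lphi
    )


def log_marginal_posterior(kappa_f: np.ndarray, ctx: PosteriorContext) -> float:
    """Marginal posterior over the free coordinates, on the feasible manifold.

    The encompassing-prior Dirac constraint is realized by assembling
    kappa_d = W kappa_f, so every point this function touches is
    thermodynamically feasible by construction (asserted to 1e-12).
    """
    kappa = assemble_full(np.asarray(kappa_f, dtype=float), ctx.decomp)
    resid = wegscheider_residuals(kappa, ctx.decomp)
    if resid.size and float(np.max(np.abs(resid))) > FEASIBILITY_TOL:
        raise AssertionError(
            f"Wegscheider residual {np.max(np.abs(resid)):.3e} exceeds "
            f"{FEASIBILITY_TOL}: assembled kappa left the feasible manifold"
        )
    return log_posterior(kappa, ctx)
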