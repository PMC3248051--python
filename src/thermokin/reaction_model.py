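"""Closed mass-action reaction networks and their concentration dynamics.

A network of ``N`` molecular species coupled through ``M`` reversible
reactions is represented by its reactant and product stoichiometry matrices
(``nu`` and ``nu'``, both N x M, non-negative integers).  Every reaction
must be reversible with strictly positive forward and reverse rate
constants: irreversible reactions are thermodynamically impossible in a
closed system.  Concentrations evolve deterministically under the
mass-action rate law,

    dx_n/dt = sum_m s_nm * rho_m(x),
    rho_m(x) = k_{2m-1} prod_i x_i^{nu_im} - k_{2m} prod_i x_i^{nu'_im},

where ``s_nm = nu'_nm - nu_nm`` is the net stoichiometry and ``rho_m`` the
net flux of reaction ``m``.  Rate constants are handled on the natural-log
scale throughout (``kappa_{2m-1} = ln k_{2m-1}`` forward, ``kappa_{2m}``
reverse).

Perturbation experiments re-run the system with one species' initial
concentration shifted by ``pi_p`` (injection when positive, knockdown when
negative); label ``0`` denotes the unperturbed experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

__all__ = [
    "ReactionNetwork",
    "KineticParameters",
    "ExperimentDesign",
    "Trajectory",
    "SimulationError",
    "initial_state",
    "net_flux",
    "ode_rhs",
    "ode_jacobian",
    "simulate",
    "steady_state",
    "conserved_moieties",
    "dense_time_grid",
]

#: default integrator tolerances (stiff-capable LSODA)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails or produces unusable output."""


@dataclass(frozen=True)
class ReactionNetwork:
    """A closed reaction network with N species and M reversible reactions."""

    species_names: tuple[str, ...]
    reactant_stoich: np.ndarray  # N x M, nu_nm >= 0
    product_stoich: np.ndarray  # N x M, nu'_nm >= 0

    def __post_init__(self) -> None:
        nu = np.asarray(self.reactant_stoich, dtype=int)
        nup = np.asarray(self.product_stoich, dtype=int)
        object.__setattr__(self, "species_names", tuple(self.species_names))
        object.__setattr__(self, "reactant_stoich", nu)
        object.__setattr__(self, "product_stoich", nup)
        if nu.ndim != 2 or nu.shape != nup.shape:
            raise ValueError("stoichiometry matrices must be N x M and congruent")
        n, m = nu.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one species and one reaction")
        if len(self.species_names) != n:
            raise ValueError("species_names length must match stoichiometry rows")
        if (nu < 0).any() or (nup < 0).any():
            raise ValueError("stoichiometric coefficients must be non-negative")
        if (nu.sum(axis=0) == 0).any() or (nup.sum(axis=0) == 0).any():
            raise ValueError(
                "every reaction needs reactants and products: a closed system "
                "admits no pure source or sink reactions"
            )

    @property
    def n_species(self) -> int:
        return self.reactant_stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.reactant_stoich.shape[1]

    @property
    def net_stoich(self) -> np.ndarray:
        """Net stoichiometry matrix S with s_nm = nu'_nm - nu_nm."""
        return self.product_stoich - self.reactant_stoich

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None


@dataclass(frozen=True)
class KineticParameters:
    """Log-rate constants kappa = (kappa_1 ... kappa_{2M}).

    Odd positions (0-based even indices) are forward log-rates, even
    positions are reverse log-rates.  All entries must be finite, which is
    equivalent to strictly positive rate constants.
    """

    kappa: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "kappa", k)
        if k.ndim != 1 or k.size % 2 != 0 or k.size == 0:
            raise ValueError("kappa must be a flat vector of length 2M")
        if not np.all(np.isfinite(k)):
            raise ValueError("log-rate constants must be finite (all k > 0)")

    @classmethod
    def from_rates(cls, rates: Sequence[float]) -> "KineticParameters":
        r = np.asarray(rates, dtype=float)
        if (r <= 0).any():
            raise ValueError("rate constants must be strictly positive")
        return cls(np.log(r))

    @property
    def n_reactions(self) -> int:
        return self.kappa.size // 2

    @property
    def rates(self) -> np.ndarray:
        return np.exp(self.kappa)

    @property
    def forward(self) -> np.ndarray:
        return self.kappa[0::2]

    @property
    def reverse(self) -> np.ndarray:
        return self.kappa[1::2]

    @property
    def z(self) -> np.ndarray:
        """Log-equilibrium constants z_m = kappa_{2m-1} - kappa_{2m}."""
        return self.forward - self.reverse


@dataclass(frozen=True)
class ExperimentDesign:
    """Initial state, perturbation set and sampling times of one study.

    ``perturbations`` maps 1-based species labels ``p`` to shifts ``pi_p``
    applied to the initial concentration of species ``p`` at time zero.
    Label 0 always denotes the unperturbed experiment and is implicit.
    """

    initial_concentrations: np.ndarray
    perturbations: Mapping[int, float] = field(default_factory=dict)
    t_max: float = 1.0
    transient_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    steady_state_time: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.initial_concentrations, dtype=float)
        tq = np.asarray(self.transient_times, dtype=float)
        object.__setattr__(self, "initial_concentrations", c)
        object.__setattr__(self, "transient_times", tq)
        object.__setattr__(self, "perturbations", dict(self.perturbations))
        if (c <= 0).any():
            raise ValueError("initial concentrations must be strictly positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        for p, pi in self.perturbations.items():
            if not 1 <= p <= c.size:
                raise KeyError(f"perturbation label {p} is not a species index")
            if c[p - 1] + pi < 0:
                raise ValueError(
                    f"infeasible perturbation pi_{p}={pi}: requires pi_p >= -c_p"
                )
        if tq.size:
            if not (np.all(np.diff(tq) > 0) and tq[0] > 0 and tq[-1] <= self.t_max):
                raise ValueError("transient times must be strictly increasing in (0, t_max]")
            if self.steady_state_time is not None and not (
                tq[-1] < self.steady_state_time <= self.t_max
            ):
                raise ValueError("steady-state time must lie in (t_Q, t_max]")

    @property
    def labels(self) -> list[int]:
        """Perturbation labels, unperturbed experiment first."""
        return [0, *self.perturbations.keys()]

    @property
    def n_perturbations(self) -> int:
        """P, the number of perturbation experiments beyond the unperturbed one."""
        return len(self.perturbations)


@dataclass(frozen=True)
class Trajectory:
    """Simulated concentrations on a time grid for one perturbation label."""

    times: np.ndarray
    concentrations: np.ndarray  # len(times) x N
    perturbation_label: int


def initial_state(design: ExperimentDesign, p: int) -> np.ndarray:
    """Initial concentration vector of experiment ``p`` (0 = unperturbed)."""
    c = design.initial_concentrations.copy()
    if p == 0:
        return c
    if p not in design.perturbations:
        raise KeyError(f"unknown perturbation label {p}; declared: {design.labels}")
    c[p - 1] += design.perturbations[p]
    return c


def net_flux(x: np.ndarray, kappa: KineticParameters, net: ReactionNetwork) -> np.ndarray:
    """Net reaction fluxes rho_m(x) under mass-action kinetics."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("concentrations must be non-negative")
    kf = np.exp(kappa.forward)
    kr = np.exp(kappa.reverse)
    fwd = np.prod(x[:, None] ** net.reactant_stoich, axis=0)
    rev = np.prod(x[:, None] ** net.product_stoich, axis=0)
    return kf * fwd - kr * rev


def ode_rhs(t: float, x: np.ndarray, kappa: KineticParameters, net: ReactionNetwork) -> np.ndarray:
    """Right-hand side of the kinetic equations, dx/dt = S rho(x)."""
    return net.net_stoich @ net_flux(x, kappa, net)


def ode_jacobian(t: float, x: np.ndarray, kappa: KineticParameters, net: ReactionNetwork) -> np.ndarray:
    """Analytic Jacobian d(dx/dt)/dx, used by the implicit integrator."""
    x = np.asarray(x, dtype=float)
    n, m = net.n_species, net.n_reactions
    kf = np.exp(kappa.forward)
    kr = np.exp(kappa.reverse)
    # d rho_m / d x_i for each stoichiometry matrix
    drho = np.zeros((m, n))
    for stoich, k, sign in ((net.reactant_stoich, kf, 1.0), (net.product_stoich, kr, -1.0)):
        for mm in range(m):
            for i in range(n):
                v = stoich[i, mm]
                if v == 0:
                    continue
                expo = stoich[:, mm].astype(float).copy()
                expo[i] -= 1.0
                with np.errstate(divide="ignore"):
                    term = np.prod(np.where(expo == 0, 1.0, x ** expo))
                drho[mm, i] += sign * k[mm] * v * term
    return net.net_stoich @ drho


try:  # optional JIT fast path for the integrator callbacks
    from numba import njit as _njit

    @_njit(cache=True)
    def _ma_rhs_kernel(x, kf, kr, nu, nup, S):  # pragma: no cover - jitted
        n = x.size
        m = kf.size
        dx = np.zeros(n)
        for j in range(m):
            f = kf[j]
            r = kr[j]
            for i in range(n):
                for _ in range(nu[i, j]):
                    f *= x[i]
                for _ in range(nup[i, j]):
                    r *= x[i]
            rho = f - r
            for i in range(n):
                dx[i] += S[i, j] * rho
        return dx

    @_njit(cache=True)
    def _ma_jac_kernel(x, kf, kr, nu, nup, S):  # pragma: no cover - jitted
        n = x.size
        m = kf.size
        J = np.zeros((n, n))
        for j in range(m):
            for i in range(n):
                d = 0.0
                if nu[i, j] > 0:
                    t = kf[j] * nu[i, j]
                    for l in range(n):
                        e = nu[l, j] - (1 if l == i else 0)
                        for _ in range(e):
                            t *= x[l]
                    d += t
                if nup[i, j] > 0:
                    t = kr[j] * nup[i, j]
                    for l in range(n):
                        e = nup[l, j] - (1 if l == i else 0)
                        for _ in range(e):
                            t *= x[l]
                    d -= t
                for row in range(n):
                    J[row, i] += S[row, j] * d
        return J

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _callbacks(net: ReactionNetwork, kappa: KineticParameters):
    """RHS/Jacobian closures with precomputed rate and stoichiometry data.

    Integrator excursions marginally below zero are clipped before they
    enter the mass-action powers (stoichiometries are integer, but
    x**nu with x < 0 flips signs for odd nu).
    """
    kf = np.exp(kappa.forward)
    kr = np.exp(kappa.reverse)
    nu = net.reactant_stoich
    nup = net.product_stoich
    S = net.net_stoich.astype(float)
    if _HAVE_NUMBA:
        nu64 = nu.astype(np.int64)
        nup64 = nup.astype(np.int64)

        def rhs(t, x):
            return _ma_rhs_kernel(np.maximum(x, 0.0), kf, kr, nu64, nup64, S)

        def jac(t, x):
            return _ma_jac_kernel(np.maximum(x, 0.0), kf, kr, nu64, nup64, S)

    else:

        def rhs(t, x):
            return ode_rhs(t, np.maximum(x, 0.0), kappa, net)

        def jac(t, x):
            return ode_jacobian(t, np.maximum(x, 0.0), kappa, net)

    return rhs, jac


def _integrate(net, kappa, x0, t_span, t_eval, rtol, atol):
    rhs, jac = _callbacks(net, kappa)
    sol = solve_ivp(
        rhs, t_span, x0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol, jac=jac
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed over t={t_span} (rtol={rtol}, atol={atol}): "
            f"{sol.message}"
        )
    return sol


def simulate(
    net: ReactionNetwork,
    kappa: KineticParameters,
    design: ExperimentDesign,
    p: int = 0,
    eval_times: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the kinetic equations for perturbation experiment ``p``.

    ``eval_times`` defaults to the 201-point dense grid over (0, t_max]
    used by the dynamics-error metrics; times must lie in [0, t_max].
    """
    x0 = initial_state(design, p)
    if eval_times is None:
        eval_times = dense_time_grid(design.t_max)
    t = np.asarray(eval_times, dtype=float)
    if t.size and (t[0] < 0 or t[-1] > design.t_max * (1 + 1e-12)):
        raise ValueError("eval_times must lie within [0, t_max]")
    need_t0 = t.size == 0 or t[0] > 0
    t_solver = np.concatenate(([0.0], t)) if need_t0 else t
    sol = _integrate(net, kappa, x0, (0.0, t_solver[-1]), t_solver, rtol, atol)
    y = sol.y.T
    if need_t0:
        y = y[1:]
    elif t.size and t[0] == 0.0:
        y = y.copy()
        y[0] = x0  # the initial state is exact, not interpolated
    return Trajectory(times=t, concentrations=y, perturbation_label=p)


def steady_state(
    net: ReactionNetwork,
    kappa: KineticParameters,
    design: ExperimentDesign,
    p: int = 0,
    flux_tol: float | None = None,
    max_doublings: int = 40,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Stationary concentrations reached from experiment ``p``'s initial state.

    Integrates on doubling horizons starting at ``t_max`` until every net
    flux magnitude falls below ``flux_tol`` (default 1e-9 times the largest
    initial total concentration).  For thermodynamically feasible rate
    constants this point satisfies detailed balance: all net fluxes vanish.
    """
    x0 = initial_state(design, p)
    if flux_tol is None:
        flux_tol = 1e-9 * float(np.sum(x0))
    horizon = design.t_max
    x = x0
    for _ in range(max_doublings):
        sol = _integrate(net, kappa, x, (0.0, horizon), None, rtol, atol)
        x = np.maximum(sol.y[:, -1], 0.0)
        resid = float(np.max(np.abs(net_flux(x, kappa, net))))
        if resid < flux_tol:
            return x
        horizon *= 2.0
    raise SimulationError(
        f"steady state not reached: max|rho| = {resid:.3e} > {flux_tol:.3e} "
        f"after horizon {horizon/2:.3g}"
    )


def conserved_moieties(net: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Rows spanning the left null space of S (conserved moiety vectors)."""
    basis = null_space(net.net_stoich.T.astype(float), rcond=tol)
    return basis.T


def dense_time_grid(t_max: float, n: int = 201) -> np.ndarray:
    """Mixed linear/geometric evaluation grid over [0, t_max].

    Half the points are linearly spaced (capturing the approach to steady
    state), half geometrically spaced from t_max/1000 (resolving fast
    transients that dominate the integrated-error criteria).
    """
    n_lin = n // 2 + 1
    n_geo = n - n_lin
    lin = np.linspace(0.0, t_max, n_lin)
    geo = np.geomspace(t_max / 1000.0, t_max, n_geo)
    return np.unique(np.concatenate((lin, geo)))
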