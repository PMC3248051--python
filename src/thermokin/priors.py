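"""Prior densities for the calibration problem.

Three prior components enter the posterior:

* an inverse-gamma prior on the measurement-error variance sigma^2
  (conjugate for the variance of additive Gaussian errors in log space);
* an Arrhenius-derived prior for each forward log-rate constant: writing
  k = alpha0 e^g * exp(-(E0+U)/(k_B T)) with a log-normal prefactor
  perturbation g ~ N(0, lambda^2) and an exponential activation-energy
  excess U with mean k_B T*, the forward log-rate is
  kappa = kappa0 + g - U/(k_B T), i.e. an exponentially modified Gaussian
  reflected to have a left tail, with tau = T*/T > 1:

      p(kappa) = e^{lambda^2/2 tau^2} / (2 tau)
                 * erfc[(lambda/tau + (kappa - kappa0)/lambda)/sqrt(2)]
                 * e^{(kappa - kappa0)/tau};

* a data-derived prior for the log-equilibrium constants z: at steady
  state z_m is a stoichiometry-weighted sum of stationary
  log-concentrations, so noisy steady-state measurements give an unbiased
  estimate y_tilde of z with a known error structure.  The resulting
  density is a multivariate Student-type form in the quadratic
  (z - y_tilde)^T theta (z - y_tilde), with theta the rank-truncated
  pseudo-inverse of H = S^T S obtained by SVD (H is typically singular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import invgamma

from .reaction_model import ReactionNetwork

__all__ = [
    "VarianceHyperparams",
    "ArrheniusHyperparams",
    "EquilibriumPriorStats",
    "variance_prior_logpdf",
    "forward_rate_prior_logpdf",
    "forward_rate_prior_mode",
    "sample_forward_rate_prior",
    "equilibrium_stats",
    "equilibrium_prior_logpdf",
    "elicit_arrhenius_hyperparams",
]


@dataclass(frozen=True)
class VarianceHyperparams:
    """Inverse-gamma hyperparameters: shape alpha, scale b.

    For alpha > 2 the prior has mean b/(alpha-1) and variance
    mean^2/(alpha-2).
    """

    alpha: float
    b: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.b <= 0:
            raise ValueError("alpha and b must be positive")

    @property
    def mean(self) -> float:
        if self.alpha <= 1:
            raise ValueError("mean undefined for alpha <= 1")
        return self.b / (self.alpha - 1)

    @property
    def variance(self) -> float:
        if self.alpha <= 2:
            raise ValueError("variance undefined for alpha <= 2")
        return self.mean**2 / (self.alpha - 2)


@dataclass(frozen=True)
class ArrheniusHyperparams:
    """Location/scale hyperparameters of the forward log-rate prior.

    kappa0 folds the predictable prefactor and activation energy
    (ln alpha0 - E0/k_B T); tau = T*/T > 1 is the mean of the exponential
    activation-energy excess on the log-rate scale; lambda is the
    standard deviation of the Gaussian prefactor perturbation.  Scalars
    are shared across reactions; arrays give per-reaction values.
    """

    kappa0: float | np.ndarray
    tau: float | np.ndarray
    lam: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tau) <= 1.0):
            raise ValueError("tau = T*/T must exceed 1")
        if np.any(np.asarray(self.lam) <= 0.0):
            raise ValueError("lambda must be positive")

    def per_reaction(self, m: int) -> tuple[float, float, float]:
        k0 = np.broadcast_to(np.asarray(self.kappa0, dtype=float), (max(m + 1, 1),))
        t = np.broadcast_to(np.asarray(self.tau, dtype=float), k0.shape)
        l = np.broadcast_to(np.asarray(self.lam, dtype=float), k0.shape)
        return float(k0[m]), float(t[m]), float(l[m])

    @property
    def mean(self):
        """Prior mean kappa0 - tau (EMG construction)."""
        return np.asarray(self.kappa0) - np.asarray(self.tau)

    @property
    def sd(self):
        """Prior standard deviation sqrt(lambda^2 + tau^2)."""
        return np.sqrt(np.asarray(self.lam) ** 2 + np.asarray(self.tau) ** 2)


@dataclass(frozen=True)
class EquilibriumPriorStats:
    """Sufficient statistics of the steady-state-derived prior on z."""

    y_tilde: np.ndarray  # length M
    theta: np.ndarray  # M x M, rank-truncated pseudo-inverse of S^T S
    P: int  # number of perturbation experiments (labels beyond 0)
    alpha: float
    b: float


def variance_prior_logpdf(sigma2: float, h: VarianceHyperparams) -> float:
    """Log-density of the inverse-gamma variance prior at sigma2 > 0."""
    sigma2 = float(sigma2)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return float(invgamma.logpdf(sigma2, a=h.alpha, scale=h.b))


def _log_erfc(u):
    """log erfc(u), stable for large positive u (via the normal log-CDF)."""
    return np.log(2.0) + log_ndtr(-np.sqrt(2.0) * u)


def forward_rate_prior_logpdf(
    kappa_odd, h: ArrheniusHyperparams, m: int = 0
):
    """Log prior density of the m-th forward log-rate constant.

    Evaluated entirely in log space; the erfc factor is computed through
    the scaled normal log-CDF so that neither the exponential prefactor
    nor the erfc tail under/overflows for arguments out to |u| ~ 40.
    """
    k0, tau, lam = h.per_reaction(m)
    kappa_odd = np.asarray(kappa_odd, dtype=float)
    u = (lam / tau + (kappa_odd - k0) / lam) / np.sqrt(2.0)
    out = (
        lam**2 / (2.0 * tau**2)
        - np.log(2.0 * tau)
        + _log_erfc(u)
        + (kappa_odd - k0) / tau
    )
    return out if out.ndim else float(out)


def forward_rate_prior_mode(h: ArrheniusHyperparams, m: int = 0) -> float:
    """Numeric mode of the forward log-rate prior (1-D bracketed search)."""
    k0, tau, lam = h.per_reaction(m)
    # mode lies between the mean (k0 - tau) and k0 + a few lambda
    res = optimize.minimize_scalar(
        lambda x: -forward_rate_prior_logpdf(x, h, m),
        bounds=(k0 - tau - 6 * lam, k0 + 6 * lam),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def sample_forward_rate_prior(
    h: ArrheniusHyperparams, m: int, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Constructive draws kappa0 + N(0, lambda^2) - Exp(mean tau)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    k0, tau, lam = h.per_reaction(m)
    return k0 + rng.normal(0.0, lam, size=count) - rng.exponential(tau, size=count)


def _theta_from_net(net: ReactionNetwork, tol: float = 1e-10) -> np.ndarray:
    """Rank-truncated SVD pseudo-inverse of H = S^T S."""
    S = net.net_stoich.astype(float)
    H = S.T @ S
    u, s, _ = np.linalg.svd(H)
    rank = int(np.sum(s > tol * s[0])) if s.size and s[0] > 0 else 0
    u0 = u[:, :rank]
    d0 = s[:rank]
    return u0 @ np.diag(1.0 / d0) @ u0.T


def equilibrium_stats(
    ybar: np.ndarray,
    net: ReactionNetwork,
    h: VarianceHyperparams,
    tol: float = 1e-10,
) -> EquilibriumPriorStats:
    """Build the steady-state prior statistics from measurements ybar.

    ``ybar`` is the N x (P+1) array of steady-state log-measurements
    (columns ordered unperturbed first).  The estimate of z is

        y_tilde_m = (1/(P+1)) sum_p sum_n s_nm ybar_n^(p),

    which is exact for noiseless data from a feasible system.
    """
    ybar = np.asarray(ybar, dtype=float)
    if ybar.ndim != 2 or ybar.shape[0] != net.n_species:
        raise ValueError("ybar must be N x (P+1)")
    if not np.all(np.isfinite(ybar)):
        raise ValueError("steady-state measurement table is incomplete (non-finite entries)")
    P = ybar.shape[1] - 1
    S = net.net_stoich.astype(float)
    y_tilde = S.T @ ybar.sum(axis=1) / (P + 1)
    theta = _theta_from_net(net, tol)
    return EquilibriumPriorStats(y_tilde=y_tilde, theta=theta, P=P, alpha=h.alpha, b=h.b)


def equilibrium_prior_logpdf(z: np.ndarray, stats: EquilibriumPriorStats) -> float:
    """Unnormalized log prior of the log-equilibrium constants.

    -alpha * log[ 2b/(P+1) + (z - y_tilde)^T theta (z - y_tilde) ].
    Directions in the null space of theta (equivalently of S^T S) leave
    the density unchanged — those components of z are informed only by
    the Arrhenius prior and the data likelihood.
    """
    d = np.asarray(z, dtype=float) - stats.y_tilde
    quad = float(d @ stats.theta @ d)
    return -stats.alpha * np.log(2.0 * stats.b / (stats.P + 1) + quad)


#: lambda/tau ratio implied by the reference hyperparameter set
_ELICIT_RATIO = 0.390


def elicit_arrhenius_hyperparams(k_low: float, k_high: float) -> ArrheniusHyperparams:
    """Map a plausible rate-constant range to prior hyperparameters.

    The prior mean kappa0 - tau is set to the midpoint of
    (ln k_low, ln k_high); the prior standard deviation
    sqrt(lambda^2 + tau^2) to a quarter of the log-range; the shape ratio
    lambda/tau is fixed at 0.390.  If the implied tau does not exceed 1
    (a very narrow range), tau is floored just above 1 and kappa0
    re-solved so the mean is preserved.
    """
    if not (0 < k_low < k_high):
        raise ValueError("need 0 < k_low < k_high")
    mu = 0.5 * (np.log(k_low) + np.log(k_high))
    sd = 0.25 * (np.log(k_high) - np.log(k_low))
    tau = sd / np.sqrt(1.0 + _ELICIT_RATIO**2)
    if tau <= 1.0:
        tau = 1.0 + 1e-9
    lam = _ELICIT_RATIO * tau
    kappa0 = mu + tau
    return ArrheniusHyperparams(kappa0=kappa0, tau=tau, lam=lam)
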