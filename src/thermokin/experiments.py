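"""Synthetic perturbation experiments: sampling schemes, noise, designs.

The generator emulates the data-formation process assumed by the
posterior: simulate the kinetic equations for the unperturbed system and
each single-species initial-concentration perturbation, record
log-concentrations at Q transient times plus one steady-state time, and
corrupt them with multiplicative error (additive in log space).  Three
error families are supported — the i.i.d. Gaussian family the likelihood
assumes, and two deliberate violations used for robustness studies:
i.i.d. uniform on [-sqrt(3) sigma, sqrt(3) sigma] (standard deviation
exactly sigma) and exponentially correlated stationary Gaussian with
cov[eta(t1), eta(t2)] = sigma^2 exp(-|t1 - t2|) (timescale fixed at one
time unit).  Transient and steady-state errors come from independently
spawned streams, honoring the independence the posterior factorization
requires (the correlated family intentionally breaks it within a
series).

``run_design`` is the design-comparison harness: generate data for each
candidate design, calibrate, and tabulate the accuracy criteria ordered
by the D-criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .inference import MCMCConfig, SPSAConfig, mem_estimate
from .metrics import AccuracyReport, d_criterion, median_max_abs_error, posterior_rmse
from .model_io import read_model
from .posterior import MeasurementSet, build_context
from .priors import ArrheniusHyperparams, VarianceHyperparams
from .reaction_model import (
    ExperimentDesign,
    KineticParameters,
    ReactionNetwork,
    simulate,
)
from .thermodynamics import decompose, project_to_feasible, wegscheider_residuals

__all__ = [
    "NoiseModel",
    "SamplingScheme",
    "FixtureUnavailableError",
    "sampling_times",
    "apply_scheme",
    "generate_measurements",
    "run_design",
    "fixture_network",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error family; sigma is the marginal standard deviation."""

    family: str = "iid_gaussian"
    sigma: float = 0.3
    correlation_timescale: float = 1.0

    _FAMILIES = ("iid_gaussian", "iid_uniform", "correlated_gaussian")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"family must be one of {self._FAMILIES}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def draw_series(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One error series over the given times (a single draw per series)."""
        times = np.asarray(times, dtype=float)
        if self.sigma == 0.0:
            return np.zeros(times.size)
        if self.family == "iid_gaussian":
            return rng.normal(0.0, self.sigma, size=times.size)
        if self.family == "iid_uniform":
            half = np.sqrt(3.0) * self.sigma
            return rng.uniform(-half, half, size=times.size)
        lag = np.abs(times[:, None] - times[None, :]) / self.correlation_timescale
        cov = self.sigma**2 * np.exp(-lag)
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(times.size))
        return chol @ rng.standard_normal(times.size)


@dataclass(frozen=True)
class SamplingScheme:
    """Placement of the Q transient times and the steady-state time.

    ``uniform`` spaces t_q = q * t_max/(Q+1); ``logarithmic`` spaces the
    Q times geometrically from t_min (default t_max/100) to
    t_max * Q/(Q+1), concentrating samples on the fast transients.  Both
    put the steady-state measurement at t_max.
    """

    kind: str = "logarithmic"
    Q: int = 6
    t_max: float = 1.0
    t_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "logarithmic"):
            raise ValueError("kind must be 'uniform' or 'logarithmic'")
        if self.Q < 2:
            raise ValueError("need Q >= 2 transient times")
        tmin = self.t_max / 100.0 if self.t_min is None else self.t_min
        if not 0 < tmin < self.t_max:
            raise ValueError("need 0 < t_min < t_max")


def sampling_times(scheme: SamplingScheme) -> tuple[np.ndarray, float]:
    """Transient times t_1..t_Q and the steady-state time t_{Q+1}."""
    Q, t_max = scheme.Q, scheme.t_max
    if scheme.kind == "uniform":
        tq = np.arange(1, Q + 1) * t_max / (Q + 1)
    else:
        t_min = t_max / 100.0 if scheme.t_min is None else scheme.t_min
        upper = t_max * Q / (Q + 1)
        tq = np.geomspace(t_min, upper, Q)
    return tq, t_max


def apply_scheme(design: ExperimentDesign, scheme: SamplingScheme) -> ExperimentDesign:
    """Attach a sampling scheme's times to a design (t_max from the design)."""
    sch = SamplingScheme(kind=scheme.kind, Q=scheme.Q, t_max=design.t_max, t_min=scheme.t_min)
    tq, t_steady = sampling_times(sch)
    return ExperimentDesign(
        initial_concentrations=design.initial_concentrations,
        perturbations=design.perturbations,
        t_max=design.t_max,
        transient_times=tq,
        steady_state_time=t_steady,
    )


def generate_measurements(
    net: ReactionNetwork,
    kappa_true: KineticParameters,
    design: ExperimentDesign,
    noise: NoiseModel,
    rng: np.random.Generator | np.random.SeedSequence | int,
    scheme: SamplingScheme | None = None,
    allow_infeasible: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MeasurementSet:
    """Simulate and corrupt one full study at the design's sampling times.

    ``kappa_true`` must satisfy the Wegscheider conditions; an infeasible
    truth is refused unless ``allow_infeasible=True`` (robustness
    studies only).  Transient and steady errors use independent spawned
    streams; for the correlated family each (species, perturbation)
    series over the Q+1 times is one multivariate draw.
    """
    if scheme is not None:
        design = apply_scheme(design, scheme)
    if design.transient_times.size == 0 or design.steady_state_time is None:
        raise ValueError("design carries no sampling times; pass a scheme")
    decomp = decompose(net)
    resid = wegscheider_residuals(kappa_true, decomp)
    if resid.size and np.max(np.abs(resid)) > 1e-9 and not allow_infeasible:
        raise ValueError(
            "kappa_true violates the Wegscheider conditions "
            f"(max residual {np.max(np.abs(resid)):.3e}); project it first "
            "or pass allow_infeasible=True"
        )
    ss = rng if isinstance(rng, np.random.SeedSequence) else (
        rng.bit_generator.seed_seq  # type: ignore[union-attr]
        if isinstance(rng, np.random.Generator)
        else np.random.SeedSequence(rng)
    )
    ss_tran, ss_steady = ss.spawn(2)
    rng_tran = np.random.default_rng(ss_tran)
    rng_steady = np.random.default_rng(ss_steady)

    tq = design.transient_times
    t_all = np.append(tq, design.steady_state_time)
    n = net.n_species
    labels = design.labels
    transient = np.empty((n, len(labels), tq.size))
    steady = np.empty((n, len(labels)))
    for j, p in enumerate(labels):
        traj = simulate(net, kappa_true, design, p, eval_times=t_all, rtol=rtol, atol=atol)
        x = traj.concentrations  # (Q+1) x N
        if np.any(x <= 0.0):
            qbad, ibad = np.argwhere(x <= 0.0)[0]
            raise ValueError(
                f"zero/negative concentration for species "
                f"{net.species_names[ibad]!r} at t={t_all[qbad]} (p={p}); "
                "log measurements are undefined"
            )
        lnx = np.log(x)
        for i in range(n):
            if noise.family == "correlated_gaussian":
                eta = noise.draw_series(t_all, rng_tran)
                transient[i, j, :] = lnx[:-1, i] + eta[:-1]
                steady[i, j] = lnx[-1, i] + eta[-1]
            else:
                transient[i, j, :] = lnx[:-1, i] + noise.draw_series(tq, rng_tran)
                steady[i, j] = lnx[-1, i] + noise.draw_series(
                    np.array([t_all[-1]]), rng_steady
                )[0]
    return MeasurementSet(
        transient=transient,
        steady=steady,
        design=design,
        transient_times=tq,
        steady_time=float(design.steady_state_time),
    )


def run_design(
    net: ReactionNetwork,
    kappa_true: KineticParameters,
    designs: dict[str, ExperimentDesign],
    scheme: SamplingScheme,
    noise: NoiseModel,
    var_hyper: VarianceHyperparams,
    arr_hyper: ArrheniusHyperparams,
    spsa_cfg: SPSAConfig | None = None,
    mcmc_cfg: MCMCConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    compute_dynamics_error: bool = True,
) -> tuple[pd.DataFrame, dict[str, AccuracyReport]]:
    """Generate-calibrate-score each candidate design; rank by D.

    Returns a table (one row per design, ordered by D ascending, i.e.
    best first) and the per-design accuracy reports.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    reports: dict[str, AccuracyReport] = {}
    rows = []
    for (label, design), ss_d in zip(designs.items(), ss.spawn(len(designs))):
        ss_data, ss_mem = ss_d.spawn(2)
        data = generate_measurements(net, kappa_true, design, noise, ss_data, scheme=scheme)
        ctx = build_context(net, data.design, data, var_hyper, arr_hyper)
        result = mem_estimate(ctx, spsa_cfg, mcmc_cfg, seed=ss_mem)
        rmse = posterior_rmse(result.samples, result.mode_f)
        D = d_criterion(result.covariance, ctx.decomp.n_free)
        med_ae = max_ae = None
        if compute_dynamics_error:
            med_ae, max_ae = median_max_abs_error(
                net, kappa_true, KineticParameters(result.kappa_hat), data.design
            )
        reports[label] = AccuracyReport(
            rmse=rmse,
            D=D,
            covariance=result.covariance,
            med_ae=med_ae,
            max_ae=max_ae,
            label=label,
            extras={
                "acceptance_rate": result.acceptance_rate,
                "best_log_posterior": result.best_log_posterior,
            },
        )
        rows.append(
            {
                "design": label,
                "Q": data.Q,
                "P": data.P,
                "D": D,
                "med_ae": med_ae,
                "max_ae": max_ae,
                "mean_rmse": float(np.mean(rmse)),
            }
        )
    table = pd.DataFrame(rows).sort_values("D").reset_index(drop=True)
    return table, reports


FIXTURE_NAMES = ("two_state", "triangle", "dimerization", "chain3", "egf_erk_subset")


class FixtureUnavailableError(FileNotFoundError):
    """A named fixture exists in the registry but has no packaged data."""


def fixture_network(
    name: str,
) -> tuple[ReactionNetwork, KineticParameters, KineticParameters, ExperimentDesign]:
    """Load a packaged fixture: (net, kappa_published, kappa_true, design).

    ``kappa_true`` is the Euclidean feasibility projection of the
    published rate set (identical when the published set already
    satisfies the Wegscheider conditions).

    The ``egf_erk_subset`` slot (N=13, M=9 reversible mass-action subset
    of the EGF/ERK cascade) requires a transcription of its supplementary
    reaction list and rate table into ``fixtures/egf_erk_subset.json``;
    until one is added the fixture raises ``FixtureUnavailableError``.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    store = resources.files("thermokin") / "fixtures" / f"{name}.json"
    if not store.is_file():
        raise FixtureUnavailableError(
            f"fixture {name!r} has no packaged model file. The EGF/ERK subset "
            "needs its published reaction list, rate constants and initial "
            "concentrations transcribed into "
            f"src/thermokin/fixtures/{name}.json (canonical model JSON schema)."
        )
    with resources.as_file(store) as path:
        net, kappa_published, design = read_model(path)
    decomp = decompose(net)
    kappa_true = project_to_feasible(kappa_published, decomp)
    return net, kappa_published, kappa_true, design
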