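"""Estimation-accuracy and experimental-design criteria.

Three summaries quantify a calibration result:

* per-parameter posterior RMSE about the mode,
  eps_RMSE = sqrt(E[(kappa_f - mode)^2 | y]), Monte Carlo estimated from
  the post-burn-in samples — only free parameters are reported (the
  dependent log-rates are deterministic functions of the free set);
* the D-criterion, ln det(V) / (M + M1), the average log-eigenvalue of
  the posterior covariance; lower is better, and it is the quantity used
  to rank sampling schemes and perturbation designs;
* when the generating system is known, the median and maximum over
  (species, perturbation) pairs of the time-integrated absolute
  concentration error normalized by the true integrated response.  By
  construction half the normalized errors lie below the median value and
  the rest between it and the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reaction_model import (
    ExperimentDesign,
    KineticParameters,
    ReactionNetwork,
    dense_time_grid,
    simulate,
)
from .thermodynamics import ThermoDecomposition

__all__ = [
    "AccuracyReport",
    "posterior_rmse",
    "d_criterion",
    "median_max_abs_error",
    "d_percent_change",
]


@dataclass
class AccuracyReport:
    """Accuracy summaries for one calibration run / design row."""

    rmse: np.ndarray  # per free parameter
    D: float
    covariance: np.ndarray
    med_ae: float | None = None
    max_ae: float | None = None
    label: str = ""
    extras: dict = field(default_factory=dict)

    def rmse_table(self, decomp: ThermoDecomposition) -> dict[str, str]:
        """kappa_i -> RMSE rows, a dash for dependent parameters."""
        out: dict[str, str] = {}
        rmse_by_index = dict(zip(decomp.free_indices, self.rmse))
        for i in range(2 * decomp.M):
            name = f"kappa_{i + 1}"
            out[name] = (
                f"{rmse_by_index[i]:.4f}" if i in rmse_by_index else "-"
            )
        return out

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "rmse": self.rmse.tolist(),
            "D": self.D,
            "med_ae": self.med_ae,
            "max_ae": self.max_ae,
            **self.extras,
        }


def posterior_rmse(samples: np.ndarray, mode_estimate: np.ndarray) -> np.ndarray:
    """Per-coordinate RMSE of the samples about the mode estimate."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need at least two posterior samples")
    dev = samples - np.asarray(mode_estimate, dtype=float)
    return np.sqrt(np.mean(dev**2, axis=0))


def d_criterion(V: np.ndarray, dim: int | None = None) -> float:
    """ln det(V) / dim via a symmetric eigendecomposition (no raw det).

    Raises on a non-positive-definite V, reporting the offending
    eigenvalue: a singular covariance means some free direction was never
    explored and the criterion is undefined.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("V must be square")
    if dim is None:
        dim = V.shape[0]
    eig = np.linalg.eigvalsh(0.5 * (V + V.T))
    if eig[0] <= 0.0:
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (eigenvalue {eig[0]:.3e})"
        )
    return float(np.sum(np.log(eig)) / dim)


def median_max_abs_error(
    net: ReactionNetwork,
    kappa_true: KineticParameters,
    kappa_hat: KineticParameters,
    design: ExperimentDesign,
    grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Median and maximum normalized integrated absolute dynamics error.

    For each species n and perturbation p,
    e_{n,p} = int |x_hat - x| dt / int x dt over the observation window,
    by composite trapezoid on the dense mixed linear/geometric grid.
    The ratio of integrals makes the criterion invariant to rescaling all
    concentrations.
    """
    if grid is None:
        grid = dense_time_grid(design.t_max)
    errors = []
    for p in design.labels:
        x_true = simulate(net, kappa_true, design, p, eval_times=grid).concentrations
        x_hat = simulate(net, kappa_hat, design, p, eval_times=grid).concentrations
        num = np.trapezoid(np.abs(x_hat - x_true), grid, axis=0)
        den = np.trapezoid(x_true, grid, axis=0)
        if np.any(den <= 0.0):
            bad = int(np.argmin(den))
            raise ZeroDivisionError(
                f"zero integrated true response for species "
                f"{net.species_names[bad]!r}, perturbation {p}"
            )
        errors.append(num / den)
    e = np.concatenate(errors)
    return float(np.median(e)), float(np.max(e))


def d_percent_change(d_values: np.ndarray) -> np.ndarray:
    """Successive percent change of the D-criterion along a design sweep.

    Convention: (D_prev - D_curr) / |D_prev| * 100, so a positive entry
    is an improvement (D decreased) and a negative entry a worsening.
    """
    d = np.asarray(d_values, dtype=float)
    if d.size < 2:
        return np.empty(0)
    return (d[:-1] - d[1:]) / np.abs(d[:-1]) * 100.0
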