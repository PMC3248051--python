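"""Wegscheider-condition machinery for closed reaction networks.

At steady state every net flux of a closed system vanishes (detailed
balance), which constrains the log-equilibrium constants
``z_m = kappa_{2m-1} - kappa_{2m}``: for every vector ``r`` in the null
space of the stoichiometry matrix ``S``, the Wegscheider condition
``r^T z = 0`` must hold.  With ``M1 = rank(S)`` this leaves an
``(M + M1)``-dimensional feasible manifold inside the 2M-dimensional
log-rate space: all M forward log-rates plus M1 reverse log-rates are
free, and the remaining ``M - M1`` reverse log-rates are the affine
function ``kappa_D = W kappa_F`` of the free ones.

This module computes the rank/null-space analysis, the free/dependent
split (choosing the dependent reverse rates by column-pivoted QR of the
constraint matrix, for numerical stability), the residuals of the
Wegscheider conditions, and the Euclidean least-squares projection of an
arbitrary (e.g. literature-compiled) rate set onto the feasible
hyperplane.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.linalg import qr, svd

from .reaction_model import KineticParameters, ReactionNetwork

__all__ = [
    "ThermoDecomposition",
    "rank_and_nullspace",
    "wegscheider_residuals",
    "decompose",
    "assemble_full",
    "project_to_feasible",
]

#: relative singular-value threshold; S is integer, so rank is unambiguous
DEFAULT_RANK_TOL = 1e-10


@dataclass(frozen=True)
class ThermoDecomposition:
    """Free/dependent split of the 2M log-rate constants.

    ``free_indices`` (size M + M1) and ``dependent_indices`` (size M - M1)
    are 0-based indices into kappa; on the feasible manifold
    ``kappa[dependent_indices] = W @ kappa[free_indices]``.
    """

    M: int
    M1: int
    null_basis: np.ndarray  # M x (M - M1), orthonormal columns
    free_indices: np.ndarray
    dependent_indices: np.ndarray
    W: np.ndarray  # (M - M1) x (M + M1)

    @property
    def n_free(self) -> int:
        return self.M + self.M1

    @property
    def n_constraints(self) -> int:
        return self.M - self.M1

    def extract_free(self, kappa: KineticParameters) -> np.ndarray:
        return kappa.kappa[self.free_indices]

    def pivot_report(self) -> dict:
        """Which reverse log-rates were made dependent (serializable)."""
        return {
            "dependent_kappa_indices_1based": [int(i) + 1 for i in self.dependent_indices],
            "dependent_reactions_1based": [int(i) // 2 + 1 for i in self.dependent_indices],
            "checksum": int(np.sum(2 ** (self.dependent_indices.astype(np.int64) % 62))),
        }

    def to_json_dict(self) -> dict:
        return {
            "M": self.M,
            "M1": self.M1,
            "free_indices": [int(i) for i in self.free_indices],
            "dependent_indices": [int(i) for i in self.dependent_indices],
            "W": self.W.tolist(),
            "pivot_report": self.pivot_report(),
        }


def rank_and_nullspace(S: np.ndarray, tol: float = DEFAULT_RANK_TOL) -> tuple[int, np.ndarray]:
    """Rank of S and an orthonormal basis of null(S) (M x (M - M1))."""
    S = np.asarray(S, dtype=float)
    u, s, vh = svd(S)
    if s.size == 0 or s[0] == 0.0:
        rank = 0
    else:
        rank = int(np.sum(s > tol * s[0]))
    null = vh[rank:].T.copy()
    return rank, null


def _constraint_matrix(null_basis: np.ndarray) -> np.ndarray:
    """Constraints on kappa itself: C kappa = 0 iff R^T z = 0.

    Row j expands null vector r_j over the interleaved (forward, reverse)
    layout: +r_jm at kappa_{2m-1}, -r_jm at kappa_{2m}.
    """
    M = null_basis.shape[0]
    n_con = null_basis.shape[1]
    C = np.zeros((n_con, 2 * M))
    C[:, 0::2] = null_basis.T
    C[:, 1::2] = -null_basis.T
    return C


def wegscheider_residuals(kappa: KineticParameters, decomp: ThermoDecomposition) -> np.ndarray:
    """Residuals r^T z over the null basis; zero iff kappa is feasible."""
    return decomp.null_basis.T @ kappa.z


def decompose(net: ReactionNetwork, tol: float = DEFAULT_RANK_TOL) -> ThermoDecomposition:
    """Free/dependent decomposition of the log-rate constants of ``net``.

    All M forward log-rates are free.  Among the reverse log-rates, the
    M - M1 made dependent are selected by column-pivoted QR of the
    constraint matrix restricted to reverse coordinates, which yields the
    best-conditioned solve for W.
    """
    S = net.net_stoich
    M = net.n_reactions
    M1, null_basis = rank_and_nullspace(S, tol)
    if M1 == 0 and np.any(S != 0):
        warnings.warn(
            "rank tolerance too coarse: rank(S)=0 for a nontrivial S; "
            "decomposition is degenerate",
            RuntimeWarning,
        )
    n_con = M - M1
    C = _constraint_matrix(null_basis)
    reverse_idx = np.arange(1, 2 * M, 2)
    if n_con == 0:
        free = np.arange(2 * M)
        return ThermoDecomposition(
            M=M,
            M1=M1,
            null_basis=null_basis,
            free_indices=free,
            dependent_indices=np.empty(0, dtype=int),
            W=np.empty((0, 2 * M)),
        )
    # pivot among reverse coordinates only: C_rev is n_con x M
    C_rev = C[:, reverse_idx]
    _, _, piv = qr(C_rev, pivoting=True)
    dependent = np.sort(reverse_idx[piv[:n_con]])
    free = np.setdiff1d(np.arange(2 * M), dependent)
    # kappa_D = -C_D^{-1} C_F kappa_F
    C_D = C[:, dependent]
    C_F = C[:, free]
    W = -np.linalg.solve(C_D, C_F)
    return ThermoDecomposition(
        M=M,
        M1=M1,
        null_basis=null_basis,
        free_indices=free,
        dependent_indices=dependent,
        W=W,
    )


def assemble_full(kappa_f: np.ndarray, decomp: ThermoDecomposition) -> KineticParameters:
    """Assemble the full feasible kappa from free coordinates."""
    kappa_f = np.asarray(kappa_f, dtype=float)
    if kappa_f.shape != (decomp.n_free,):
        raise ValueError(
            f"expected {decomp.n_free} free coordinates, got {kappa_f.shape}"
        )
    kappa = np.empty(2 * decomp.M)
    kappa[decomp.free_indices] = kappa_f
    if decomp.n_constraints:
        kappa[decomp.dependent_indices] = decomp.W @ kappa_f
    return KineticParameters(kappa)


def project_to_feasible(
    kappa_published: KineticParameters, decomp: ThermoDecomposition
) -> KineticParameters:
    """Euclidean projection of a rate set onto the feasible hyperplane.

    Solves ``argmin ||kappa - kappa_published||_2`` subject to the
    Wegscheider conditions — the standard way to turn literature-compiled
    (usually infeasible) rate constants into a thermodynamically
    consistent "true" set.  Idempotent; feasible inputs pass through
    unchanged.
    """
    k0 = kappa_published.kappa
    if decomp.n_constraints == 0:
        return KineticParameters(k0.copy())
    C = _constraint_matrix(decomp.null_basis)
    # kappa = k0 - C^T (C C^T)^{-1} C k0
    correction = C.T @ np.linalg.solve(C @ C.T, C @ k0)
    return KineticParameters(k0 - correction)
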