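"""Average controllability of a linear network model.

The brain network is modeled as a discrete-time linear time-invariant
system x(t+1) = A x(t) + B u(t), where A is the (stabilized) connectivity
matrix, x(t) the regional activity state, and u(t) an external control
input applied through B. For a single control node kappa, B is the
indicator vector b_kappa, and the controllability Gramian

    W_kappa = sum_{tau >= 0} A^tau b_kappa b_kappa^T (A^T)^tau

is finite precisely when A is Schur stable (spectral radius < 1); it is the
unique solution of the discrete Lyapunov equation W = A W A^T + b b^T.
Average controllability of node kappa is trace(W_kappa): the aggregate
response energy the network can reach from impulses at kappa, and the
established scalar used to rank regions by their capacity to steer
whole-brain dynamics. Its value is always >= 1 because the tau = 0 term
contributes trace(b b^T) = 1.

Stability is enforced by the standard normalization A -> A / (c + sigma_max)
with c = 1, which bounds the largest singular value strictly below 1 for
any input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .connectivity import ConnectivityMatrix

__all__ = [
    "LinearSystemModel",
    "ControllabilityGramian",
    "ControllabilityProfile",
    "stabilize_adjacency",
    "node_gramian",
    "average_controllability_profile",
    "truncated_sum_oracle",
]

_RESIDUAL_TOL = 1e-8
_PSD_TOL = 1e-10


@dataclass(frozen=True)
class LinearSystemModel:
    """Stabilized system matrix for discrete LTI dynamics."""

    a_stable: np.ndarray
    normalization_constant: float
    region_labels: list[str]

    @property
    def n_regions(self) -> int:
        return self.a_stable.shape[0]

    def spectral_norm(self) -> float:
        return float(np.linalg.norm(self.a_stable, 2))

    def require_stable(self) -> None:
        s = self.spectral_norm()
        if s >= 1.0:
            raise ValueError(f"system is not Schur stable: largest singular value {s} >= 1")


@dataclass(frozen=True)
class ControllabilityGramian:
    """Single-node Gramian with its Lyapunov residual."""

    node_index: int
    selector: np.ndarray
    w: np.ndarray
    residual: float


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-region average controllability for one subject."""

    subject_id: str
    group_label: int
    values: np.ndarray
    region_labels: list[str]


def stabilize_adjacency(fc: ConnectivityMatrix | np.ndarray, c: float = 1.0,
                        subject_id: str = "", group_label: int = 0) -> LinearSystemModel:
    """Normalize an adjacency matrix into a Schur-stable system matrix.

    a_stable = A / (c + sigma_max(A)); the largest singular value of the
    result is sigma_max/(c + sigma_max) < 1 for any c > 0.
    """
    if c <= 0:
        raise ValueError("normalization constant c must be positive")
    if isinstance(fc, ConnectivityMatrix):
        fc.validate()
        a = fc.values
        labels = list(fc.region_labels)
    else:
        a = np.asarray(fc, dtype=float)
        labels = [f"ROI_{i + 1:03d}" for i in range(a.shape[0])]
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.all(np.isfinite(a)):
        raise ValueError("adjacency contains non-finite entries")
    sigma_max = float(np.linalg.norm(a, 2)) if a.size else 0.0
    divisor = c + sigma_max
    return LinearSystemModel(a_stable=a / divisor, normalization_constant=divisor, region_labels=labels)


def _selector(n: int, node: int) -> np.ndarray:
    if not 0 <= node < n:
        raise ValueError(f"node index {node} outside [0, {n})")
    b = np.zeros(n)
    b[node] = 1.0
    return b


def node_gramian(model: LinearSystemModel, node: int) -> ControllabilityGramian:
    """Solve W = A W A^T + b b^T for the single-node Gramian.

    The closed-form Lyapunov solution equals the infinite series; the
    returned residual is the Frobenius norm of the equation defect.
    """
    model.require_stable()
    a = model.a_stable
    b = _selector(model.n_regions, node)
    q = np.outer(b, b)
    w = solve_discrete_lyapunov(a, q)
    w = (w + w.T) / 2.0
    residual = float(np.linalg.norm(a @ w @ a.T + q - w, "fro"))
    return ControllabilityGramian(node_index=node, selector=b, w=w, residual=residual)


def average_controllability_profile(
    model: LinearSystemModel, subject_id: str = "", group_label: int = 0
) -> ControllabilityProfile:
    """trace(W_kappa) for every region kappa of a stable model.

    For a symmetric system matrix A = V diag(lambda) V^T the trace has the
    closed form trace(W_kappa) = sum_i V[kappa, i]^2 / (1 - lambda_i^2),
    which computes the whole profile from one eigendecomposition. General
    (non-symmetric) matrices fall back to per-node Lyapunov solves.
    """
    model.require_stable()
    a = model.a_stable
    n = model.n_regions
    if np.abs(a - a.T).max(initial=0.0) <= 1e-10:
        evals, evecs = np.linalg.eigh((a + a.T) / 2.0)
        gain = 1.0 / (1.0 - evals**2)
        values = (evecs**2) @ gain
    else:
        values = np.array([float(np.trace(node_gramian(model, k).w)) for k in range(n)])
    return ControllabilityProfile(
        subject_id=subject_id,
        group_label=group_label,
        values=values,
        region_labels=list(model.region_labels),
    )


def truncated_sum_oracle(model: LinearSystemModel, node: int, n_terms: int) -> np.ndarray:
    """Direct evaluation of the Gramian series up to n_terms terms.

    Sum_{tau=0}^{n_terms-1} A^tau b b^T (A^T)^tau by repeated
    multiplication. Kept as an independent check on the Lyapunov route.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    a = model.a_stable
    v = _selector(model.n_regions, node)
    total = np.outer(v, v)
    for _ in range(1, n_terms):
        v = a @ v
        total = total + np.outer(v, v)
    return total
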