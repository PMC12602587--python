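"""Exact representation and evaluation of the Ising model for binary data.

The model places a probability distribution over binary response patterns
``y`` in ``{0, 1}^m``:

    Pr(Y = y) = exp(sum_i tau_i y_i + sum_{i<j} omega_ij y_i y_j) / Z

where ``tau_i`` is the threshold of node ``i`` (its preference for being 1),
``omega_ij`` the pairwise interaction between nodes ``i`` and ``j``, and
``Z`` the partition function summing the unnormalised potential over all
``2^m`` patterns.  When data have been selected on a minimum sum score
``s = sum_i y_i >= k``, patterns below the cutoff are impossible, and the
appropriate normaliser is the truncated partition function ``Z^(k)`` summing
only over patterns with ``s >= k``.  Everything here is computed by exact
enumeration in log space; no approximate inference is offered.

Binary variables are coded 0/1 (absent/present), not the -1/+1 physics
convention; each unordered pair contributes a single interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import (
    DimensionMismatchError,
    EmptySupportError,
    EnumerationCapError,
    NonBinaryError,
    ValidationError,
)

#: Default hard cap on exact enumeration (2^20 ~ 1e6 states).
DEFAULT_MAX_NODES = 20

__all__ = [
    "IsingModel",
    "TruncatedSupport",
    "enumerate_states",
    "enumerate_support",
    "potential",
    "log_potential",
    "log_partition",
    "log_partition_truncated",
    "conditional_pmf",
    "pattern_log_probabilities",
    "sum_score",
    "DEFAULT_MAX_NODES",
]


@dataclass(frozen=True)
class IsingModel:
    """An Ising model: thresholds ``tau`` and symmetric pairwise weights ``omega``.

    Parameters
    ----------
    tau : array-like of shape (m,)
        Node thresholds on the log scale.
    omega : array-like of shape (m, m)
        Symmetric interaction matrix with an exactly zero diagonal.
    """

    tau: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        omega = np.asarray(self.omega, dtype=float)
        if tau.ndim != 1:
            raise ValidationError("tau must be a 1-D vector")
        m = tau.shape[0]
        if m < 1:
            raise ValidationError("model needs at least one node")
        if omega.shape != (m, m):
            raise DimensionMismatchError(
                f"omega has shape {omega.shape}, expected ({m}, {m})"
            )
        if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(omega))):
            raise ValidationError("tau and omega must be finite")
        if not np.array_equal(omega, omega.T):
            raise ValidationError("omega must be symmetric")
        if np.any(np.diag(omega) != 0):
            raise ValidationError("omega must have an exactly zero diagonal")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "omega", omega)

    @property
    def m(self) -> int:
        """Number of nodes."""
        return self.tau.shape[0]

    def permuted(self, perm) -> "IsingModel":
        """Return the model with nodes relabelled by ``perm`` (an index array)."""
        perm = np.asarray(perm)
        return IsingModel(self.tau[perm], self.omega[np.ix_(perm, perm)])


@dataclass(frozen=True)
class TruncatedSupport:
    """All binary patterns of length ``m`` with sum score at least ``k``.

    ``patterns`` is ordered lexicographically with node 1 as the most
    significant bit, so the ordering is deterministic and serialisable.
    """

    m: int
    k: int
    patterns: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.patterns.shape[0]

    @property
    def sum_scores(self) -> np.ndarray:
        return self.patterns.sum(axis=1)


def _check_cap(m: int, max_nodes: int) -> None:
    if m > max_nodes:
        raise EnumerationCapError(
            f"exact enumeration over 2^{m} states exceeds the cap of "
            f"{max_nodes} nodes; pass max_nodes explicitly to override"
        )


def enumerate_states(m: int, max_nodes: int = DEFAULT_MAX_NODES) -> np.ndarray:
    """All ``2^m`` binary patterns, lexicographic, node 1 as most significant bit."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    _check_cap(m, max_nodes)
    idx = np.arange(2**m, dtype=np.int64)
    return ((idx[:, None] >> np.arange(m - 1, -1, -1)) & 1).astype(np.int8)


def enumerate_support(
    m: int, k: int, max_nodes: int = DEFAULT_MAX_NODES
) -> TruncatedSupport:
    """Materialise the truncated support: every pattern with sum score >= ``k``."""
    if k > m:
        raise EmptySupportError(f"cutoff k={k} exceeds node count m={m}: empty support")
    if k < 0:
        raise ValidationError("k must be >= 0")
    states = enumerate_states(m, max_nodes=max_nodes)
    kept = states[states.sum(axis=1) >= k]
    return TruncatedSupport(m=m, k=k, patterns=kept)


def _as_pattern(model: IsingModel, y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1 or y.shape[0] != model.m:
        raise DimensionMismatchError(
            f"pattern has length {y.shape}, model has m={model.m}"
        )
    if not np.isin(y, (0, 1)).all():
        raise NonBinaryError("pattern entries must be 0 or 1")
    return y.astype(float)


def sum_score(y) -> int:
    """Sum score of a pattern: the number of 1 entries."""
    return int(np.asarray(y).sum())


def _log_potentials(model: IsingModel, Y: np.ndarray) -> np.ndarray:
    """Row-wise log potentials for a stack of patterns (each pair counted once)."""
    Yf = Y.astype(float)
    return Yf @ model.tau + 0.5 * np.einsum("pi,ij,pj->p", Yf, model.omega, Yf)


def log_potential(model: IsingModel, y) -> float:
    """Log of the unnormalised probability of a single pattern."""
    yv = _as_pattern(model, y)
    return float(yv @ model.tau + 0.5 * yv @ model.omega @ yv)


def potential(model: IsingModel, y) -> float:
    """Unnormalised probability exp(sum_i tau_i y_i + sum_{i<j} omega_ij y_i y_j)."""
    return float(np.exp(log_potential(model, y)))


def log_partition(model: IsingModel, max_nodes: int = DEFAULT_MAX_NODES) -> float:
    """log Z: log-sum-exp of the log potentials over all ``2^m`` patterns."""
    states = enumerate_states(model.m, max_nodes=max_nodes)
    return float(logsumexp(_log_potentials(model, states)))


def log_partition_truncated(
    model: IsingModel, k: int, max_nodes: int = DEFAULT_MAX_NODES
) -> float:
    """log Z^(k): log-sum-exp of log potentials over patterns with sum score >= k."""
    support = enumerate_support(model.m, k, max_nodes=max_nodes)
    return float(logsumexp(_log_potentials(model, support.patterns)))


def conditional_pmf(
    model: IsingModel, y, k: int = 0, max_nodes: int = DEFAULT_MAX_NODES
) -> float:
    """Pr(Y = y | s >= k): zero below the cutoff, potential / Z^(k) above it."""
    yv = _as_pattern(model, y)
    if k < 0 or k > model.m:
        raise EmptySupportError(f"cutoff k={k} outside [0, m={model.m}]")
    if yv.sum() < k:
        return 0.0
    logZk = log_partition_truncated(model, k, max_nodes=max_nodes)
    return float(np.exp(log_potential(model, y) - logZk))


def pattern_log_probabilities(
    model: IsingModel, support: TruncatedSupport
) -> np.ndarray:
    """Normalised log probabilities of every pattern in a truncated support."""
    lp = _log_potentials(model, support.patterns)
    return lp - logsumexp(lp)
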