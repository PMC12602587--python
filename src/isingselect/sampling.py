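"""Exact, seeded sampling from the full and sum-score-conditioned Ising model.

Both samplers enumerate the relevant support, compute the exact pattern
probabilities, and draw categorically.  Sampling from the conditional
distribution directly (rather than rejection sampling from the full model)
makes the post-selection sample size the thing being controlled, which is
how selection-based designs report ``n``, and its cost does not blow up when
``P(s >= k)`` is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NonBinaryError, RowBelowCutoffError, ValidationError
from .model import (
    DEFAULT_MAX_NODES,
    IsingModel,
    enumerate_support,
    pattern_log_probabilities,
)

__all__ = ["BinaryDataset", "sample_full", "sample_truncated"]


@dataclass
class BinaryDataset:
    """An n x m matrix of binary observations.

    ``cutoff`` records the sum-score selection under which rows were retained
    (``None`` when no selection is claimed); ``seed`` is sampling provenance.
    """

    data: np.ndarray
    cutoff: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValidationError("data must be a 2-D matrix")
        if not np.isin(data, (0, 1)).all():
            bad = np.argwhere(~np.isin(data, (0, 1)))[0]
            raise NonBinaryError(
                f"non-binary entry at row {bad[0]}, column {bad[1]}"
            )
        data = data.astype(np.int8)
        if self.cutoff is not None:
            sums = data.sum(axis=1)
            below = np.flatnonzero(sums < self.cutoff)
            if below.size:
                raise RowBelowCutoffError(
                    f"row {below[0]} has sum score {sums[below[0]]} < cutoff "
                    f"{self.cutoff}"
                )
        self.data = data

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    def sum_scores(self) -> np.ndarray:
        return self.data.sum(axis=1)


def _draw(model: IsingModel, n: int, k: int, seed, max_nodes: int) -> np.ndarray:
    support = enumerate_support(model.m, k, max_nodes=max_nodes)
    logp = pattern_log_probabilities(model, support)
    if not np.all(np.isfinite(logp)) and not np.any(np.isfinite(logp)):
        raise ValidationError("all retained potentials underflowed to zero mass")
    rng = np.random.default_rng(seed)
    idx = rng.choice(support.size, size=n, p=np.exp(logp))
    return support.patterns[idx]


def sample_full(
    model: IsingModel, n: int, seed, max_nodes: int = DEFAULT_MAX_NODES
) -> BinaryDataset:
    """Draw ``n`` i.i.d. patterns from the exact joint Ising distribution.

    Deterministic given ``(model, n, seed)``: the full state space is
    enumerated and rows are drawn categorically from the exact pmf.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    return BinaryDataset(_draw(model, n, 0, seed, max_nodes), cutoff=None, seed=seed)


def sample_truncated(
    model: IsingModel, n: int, k: int, seed, max_nodes: int = DEFAULT_MAX_NODES
) -> BinaryDataset:
    """Draw ``n`` i.i.d. patterns from Pr(Y = y | s >= k).

    ``n`` is the post-selection sample size; every returned row has sum
    score at least ``k`` and the dataset records ``cutoff=k``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    return BinaryDataset(_draw(model, n, k, seed, max_nodes), cutoff=k, seed=seed)
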