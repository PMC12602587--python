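"""The container every estimator returns, plus its JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Estimated Ising model plus estimation metadata.

    Attributes
    ----------
    method : str
        One of ``"multivariate"``, ``"nodewise"``, ``"elasso"``.
    corrected : bool
        Whether the sum-score selection correction was applied.
    k : int
        Cutoff used by the likelihood (0 for uncorrected fits).
    tau_hat, omega_hat : ndarray
        Estimated thresholds and symmetric zero-diagonal weight matrix.
    edge_mask : ndarray of bool
        Included edges; wherever False, ``omega_hat`` is exactly 0.
    tuning : dict
        alpha / gamma / path metadata.
    loglik : float or None
        Maximised (pseudo-)log-likelihood, when available.
    converged : bool
    se_omega : ndarray or None
        Symmetric matrix of edge standard errors, when computed.
    diagnostics : dict
        Dropped-row counts, separation flags, warnings.
    """

    method: str
    corrected: bool
    k: int
    tau_hat: np.ndarray
    omega_hat: np.ndarray
    edge_mask: np.ndarray
    tuning: dict = field(default_factory=dict)
    loglik: Optional[float] = None
    converged: bool = True
    se_omega: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tau_hat = np.asarray(self.tau_hat, dtype=float)
        self.omega_hat = np.asarray(self.omega_hat, dtype=float)
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        m = self.tau_hat.shape[0]
        if self.omega_hat.shape != (m, m) or self.edge_mask.shape != (m, m):
            raise ValidationError("omega_hat and edge_mask must be m x m")
        if not np.allclose(self.omega_hat, self.omega_hat.T):
            raise ValidationError("omega_hat must be symmetric")
        if np.any(np.diag(self.omega_hat) != 0):
            raise ValidationError("omega_hat diagonal must be exactly zero")
        if np.any(self.omega_hat[~self.edge_mask] != 0):
            raise ValidationError("masked-out edges must have weight exactly 0")
        if self.se_omega is not None:
            self.se_omega = np.asarray(self.se_omega, dtype=float)

    @property
    def m(self) -> int:
        return self.tau_hat.shape[0]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "corrected": self.corrected,
            "k": self.k,
            "tau_hat": self.tau_hat.tolist(),
            "omega_hat": self.omega_hat.tolist(),
            "edge_mask": self.edge_mask.astype(int).tolist(),
            "tuning": self.tuning,
            "loglik": self.loglik,
            "converged": self.converged,
            "se_omega": None if self.se_omega is None else self.se_omega.tolist(),
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            method=d["method"],
            corrected=d["corrected"],
            k=d["k"],
            tau_hat=np.asarray(d["tau_hat"], dtype=float),
            omega_hat=np.asarray(d["omega_hat"], dtype=float),
            edge_mask=np.asarray(d["edge_mask"], dtype=bool),
            tuning=d.get("tuning", {}),
            loglik=d.get("loglik"),
            converged=d.get("converged", True),
            se_omega=None
            if d.get("se_omega") is None
            else np.asarray(d["se_omega"], dtype=float),
            diagnostics=d.get("diagnostics", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
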