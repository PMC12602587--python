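"""Multivariate maximum-likelihood estimation of the Ising model.

The Ising model is a (curved-free) exponential family with sufficient
statistics ``(y_i)`` and ``(y_i y_j, i<j)``.  On data selected at a minimum
sum score ``k``, the corrected likelihood replaces the partition function
``Z`` with the truncated ``Z^(k)`` summing only over admissible patterns;
the uncorrected ("estimation as usual") fit keeps the full normaliser.
Because the support is enumerated exactly, the gradient (observed minus
model-expected sufficient statistics) and the information matrix
(model covariance of the sufficient statistics) are exact, and the negative
log-likelihood is smooth and convex.

Edges can be pruned by a single remove-then-refit pass of Wald tests, with
standard errors from the inverse observed information.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateNodeError,
    DimensionMismatchError,
    RowBelowCutoffError,
    SingularInformationError,
    ValidationError,
)
from .model import (
    DEFAULT_MAX_NODES,
    IsingModel,
    enumerate_support,
    log_partition_truncated,
    log_potential,
)
from .results import FitResult
from .sampling import BinaryDataset

__all__ = [
    "MultivariateIsing",
    "neg_log_likelihood",
    "fit_ml",
    "standard_errors",
    "prune",
]


def _pair_indices(m: int):
    return np.triu_indices(m, k=1)


def _suff_stats(Y: np.ndarray) -> np.ndarray:
    """Per-row sufficient statistics: the m node values then the m(m-1)/2 products."""
    Yf = np.asarray(Y, dtype=float)
    iu, ju = _pair_indices(Yf.shape[1])
    return np.hstack([Yf, Yf[:, iu] * Yf[:, ju]])


def _unpack(theta: np.ndarray, m: int):
    tau = theta[:m]
    omega = np.zeros((m, m))
    iu, ju = _pair_indices(m)
    omega[iu, ju] = theta[m:]
    return tau, omega + omega.T


def _pack(tau: np.ndarray, omega: np.ndarray) -> np.ndarray:
    iu, ju = _pair_indices(tau.shape[0])
    return np.concatenate([tau, omega[iu, ju]])


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, BinaryDataset):
        return data.data
    return BinaryDataset(np.asarray(data)).data


def neg_log_likelihood(
    model: IsingModel, data, k: int = 0, max_nodes: int = DEFAULT_MAX_NODES
) -> float:
    """Negative log-likelihood of ``data`` under the k-truncated Ising model.

    Every row must have sum score >= k; a row below the cutoff has zero
    probability under the conditional model and raises an error naming it.
    """
    X = _as_matrix(data)
    if X.shape[1] != model.m:
        raise DimensionMismatchError(
            f"data has {X.shape[1]} columns, model has m={model.m}"
        )
    sums = X.sum(axis=1)
    below = np.flatnonzero(sums < k)
    if below.size:
        raise RowBelowCutoffError(
            f"row {below[0]} has sum score {sums[below[0]]} < k={k}; its "
            "probability is zero under the conditional model"
        )
    logZk = log_partition_truncated(model, k, max_nodes=max_nodes)
    lp = np.array([log_potential(model, row) for row in X])
    return float(-(lp - logZk).sum())


class MultivariateIsing(BaseEstimator):
    """Maximum-likelihood Ising estimator with optional sum-score correction.

    Parameters
    ----------
    k : int, default=0
        Sum-score cutoff the data were selected on.
    corrected : bool, default=True
        If True the likelihood is normalised over patterns with ``s >= k``
        (the selection-bias correction); if False the full-state normaliser
        is used even on truncated data (the biased "as usual" baseline).
    prune_alpha : float or None, default=None
        If set, one Wald prune-then-refit pass at this significance level.
    ridge : float, default=0.0
        Optional L2 penalty (per observation) for near-degenerate truncated
        data; off by default.
    tol : float, default=1e-6
        Gradient-norm (mean sufficient-statistic scale) optimizer tolerance.
    max_iter : int, default=500
    max_nodes : int, default=20
        Exact-enumeration cap.

    Attributes
    ----------
    tau_ : ndarray of shape (m,)
    omega_ : ndarray of shape (m, m)
    edge_mask_ : ndarray of bool of shape (m, m)
    se_omega_ : ndarray of shape (m, m)
        NaN outside the estimated edge set.
    loglik_ : float
    converged_ : bool
    result_ : FitResult
    """

    #: declared gradient tolerance below which a fit counts as converged
    _CONV_TOL = 1e-5

    def __init__(
        self,
        k: int = 0,
        corrected: bool = True,
        prune_alpha=None,
        ridge: float = 0.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        max_nodes: int = DEFAULT_MAX_NODES,
    ):
        self.k = k
        self.corrected = corrected
        self.prune_alpha = prune_alpha
        self.ridge = ridge
        self.tol = tol
        self.max_iter = max_iter
        self.max_nodes = max_nodes

    # -- core numerics -----------------------------------------------------

    def _effective_k(self) -> int:
        return self.k if self.corrected else 0

    def _fit_theta(self, obs_mean, T, init_theta, free):
        """Maximise the truncated likelihood over the free parameters.

        ``T`` is the support-by-parameter sufficient-statistic matrix,
        ``obs_mean`` the observed mean sufficient statistics, ``free`` a
        boolean mask over the packed parameter vector (masked entries are
        held at zero).
        """
        d = obs_mean.shape[0]

        def objective(theta_free):
            theta = np.zeros(d)
            theta[free] = theta_free
            energies = T @ theta
            logZ = logsumexp(energies)
            p = np.exp(energies - logZ)
            model_mean = p @ T
            f = logZ - obs_mean @ theta
            g = model_mean - obs_mean
            if self.ridge:
                f += 0.5 * self.ridge * theta @ theta
                g = g + self.ridge * theta
            return f, g[free]

        x0 = init_theta[free]
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol * 1e-2,
                     "ftol": 1e-14},
        )
        x = res.x

        # Newton polish: quasi-Newton stalls above tolerance when the
        # information matrix is ill-conditioned; the exact Hessian (the
        # truncated-model covariance of the sufficient statistics) is cheap.
        f, g = objective(x)
        for _ in range(50):
            if not g.size or np.max(np.abs(g)) <= 0.1 * self._CONV_TOL:
                break
            theta = np.zeros(d)
            theta[free] = x
            _, _, cov = self._moments(theta, T)
            H = cov[np.ix_(free, free)]
            if self.ridge:
                H = H + self.ridge * np.eye(H.shape[0])
            try:
                step = np.linalg.solve(
                    H + 1e-10 * np.eye(H.shape[0]), g
                )
            except np.linalg.LinAlgError:
                break
            stepsize = 1.0
            for _ in range(30):
                f_new, g_new = objective(x - stepsize * step)
                if f_new <= f:
                    break
                stepsize *= 0.5
            else:
                break
            x = x - stepsize * step
            f, g = f_new, g_new

        theta = np.zeros(d)
        theta[free] = x
        grad_norm = float(np.max(np.abs(g))) if g.size else 0.0
        converged = grad_norm <= self._CONV_TOL
        return theta, grad_norm, converged

    def _moments(self, theta, T):
        """Truncated-model probabilities, mean and covariance of suff stats."""
        energies = T @ theta
        p = np.exp(energies - logsumexp(energies))
        mean = p @ T
        cov = (T * p[:, None]).T @ T - np.outer(mean, mean)
        return p, mean, cov

    def _se_from_cov(self, cov, free, n, m):
        """Edge standard errors from the inverse observed information."""
        info = n * cov[np.ix_(free, free)]
        if self.ridge:
            info = info + n * self.ridge * np.eye(info.shape[0])
        cond = float(np.linalg.cond(info))
        try:
            cov_theta = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(
                f"observed information is singular (cond={cond:.3g}); some "
                "parameters are not identified by the truncated data"
            ) from exc
        var = np.diag(cov_theta)
        if np.any(var <= 0):
            raise SingularInformationError(
                "non-positive variance from the observed information; "
                f"condition number {cond:.3g}"
            )
        se_free = np.sqrt(var)
        d = free.shape[0]
        se_full = np.full(d, np.nan)
        se_full[free] = se_free
        iu, ju = _pair_indices(m)
        se_omega = np.full((m, m), np.nan)
        se_omega[iu, ju] = se_full[m:]
        se_omega[ju, iu] = se_full[m:]
        return se_omega, cond

    def _fit_once(self, X, edge_mask):
        n, m = X.shape
        keff = self._effective_k()
        support = enumerate_support(m, keff, max_nodes=self.max_nodes)
        T = _suff_stats(support.patterns)
        obs_mean = _suff_stats(X).mean(axis=0)

        pbar = np.clip(X.mean(axis=0), 1e-3, 1 - 1e-3)
        init = np.concatenate([np.log(pbar / (1 - pbar)), np.zeros(m * (m - 1) // 2)])

        iu, ju = _pair_indices(m)
        free = np.concatenate([np.ones(m, dtype=bool), edge_mask[iu, ju]])

        theta, grad_norm, converged = self._fit_theta(obs_mean, T, init, free)
        _, _, cov = self._moments(theta, T)
        tau, omega = _unpack(theta, m)
        omega[~edge_mask] = 0.0
        np.fill_diagonal(omega, 0.0)
        loglik = float(n * (obs_mean @ theta - logsumexp(T @ theta)))
        return tau, omega, cov, free, loglik, grad_norm, converged

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the model to an n x m binary matrix (or BinaryDataset)."""
        Xm = _as_matrix(X)
        n, m = Xm.shape
        if self.k < 0 or self.k > m:
            raise ValidationError(f"k={self.k} outside [0, {m}]")
        sums = Xm.sum(axis=1)
        below = np.flatnonzero(sums < self.k)
        if below.size:
            raise RowBelowCutoffError(
                f"row {below[0]} has sum score {sums[below[0]]} < k={self.k}"
            )
        col_mean = Xm.mean(axis=0)
        degenerate = np.flatnonzero((col_mean == 0) | (col_mean == 1))
        if degenerate.size:
            raise DegenerateNodeError(
                degenerate.tolist(),
                f"node(s) {degenerate.tolist()} are constant in the data; "
                "their parameters are not estimable",
            )

        mask = ~np.eye(m, dtype=bool)
        tau, omega, cov, free, loglik, grad_norm, converged = self._fit_once(Xm, mask)
        if not converged:
            warnings.warn(
                f"optimizer did not reach gradient tolerance ({grad_norm:.2e})",
                stacklevel=2,
            )
        se_omega, cond = self._se_from_cov(cov, free, n, m)
        diagnostics = {"grad_norm": grad_norm, "info_condition_number": cond}

        if self.prune_alpha is not None and converged:
            tau, omega, mask, se_omega, loglik, converged, diagnostics = self._prune(
                Xm, tau, omega, se_omega, mask, diagnostics
            )

        self.n_features_in_ = m
        self.tau_ = tau
        self.omega_ = omega
        self.edge_mask_ = mask & ~np.eye(m, dtype=bool)
        self.se_omega_ = se_omega
        self.loglik_ = loglik
        self.converged_ = converged
        self.result_ = FitResult(
            method="multivariate",
            corrected=self.corrected,
            k=self.k,
            tau_hat=tau,
            omega_hat=omega,
            edge_mask=self.edge_mask_,
            tuning={
                "prune_alpha": self.prune_alpha,
                "ridge": self.ridge,
                "normalizer_k": self._effective_k(),
            },
            loglik=loglik,
            converged=converged,
            se_omega=se_omega,
            diagnostics=diagnostics,
        )
        return self

    def _prune(self, Xm, tau, omega, se_omega, mask, diagnostics):
        """One Wald prune-then-refit pass at ``prune_alpha``."""
        from scipy.stats import norm

        n, m = Xm.shape
        iu, ju = _pair_indices(m)
        z = np.zeros((m, m))
        with np.errstate(invalid="ignore", divide="ignore"):
            z[iu, ju] = omega[iu, ju] / se_omega[iu, ju]
        pvals = 2 * norm.sf(np.abs(z[iu, ju]))
        keep = pvals <= self.prune_alpha
        new_mask = np.zeros((m, m), dtype=bool)
        new_mask[iu[keep], ju[keep]] = True
        new_mask |= new_mask.T
        diagnostics = dict(diagnostics, n_pruned=int((~keep).sum()))
        if keep.all():
            return tau, omega, mask, se_omega, self.loglik_if(Xm, tau, omega), True, diagnostics

        tau, omega, cov, free, loglik, grad_norm, converged = self._fit_once(
            Xm, new_mask
        )
        se_omega, cond = self._se_from_cov(cov, free, n, m)
        diagnostics["grad_norm_refit"] = grad_norm
        diagnostics["info_condition_number"] = cond
        return tau, omega, new_mask, se_omega, loglik, converged, diagnostics

    def loglik_if(self, Xm, tau, omega):
        model = IsingModel(tau, omega)
        return -neg_log_likelihood(
            model, Xm, self._effective_k(), max_nodes=self.max_nodes
        )

    def score(self, X, y=None):
        """Mean log-likelihood per observation under the fitted model."""
        model = IsingModel(self.tau_, self.omega_)
        Xm = _as_matrix(X)
        return -neg_log_likelihood(
            model, Xm, self._effective_k(), max_nodes=self.max_nodes
        ) / Xm.shape[0]


# -- thin functional wrappers ---------------------------------------------


def fit_ml(
    data,
    k=None,
    *,
    corrected: bool = True,
    prune_alpha=None,
    ridge: float = 0.0,
    max_nodes: int = DEFAULT_MAX_NODES,
    **options,
) -> FitResult:
    """Corrected (or uncorrected) multivariate ML fit; returns a FitResult.

    ``k`` defaults to the dataset's recorded cutoff (0 if none).
    """
    if k is None:
        k = data.cutoff if isinstance(data, BinaryDataset) and data.cutoff else 0
    est = MultivariateIsing(
        k=k,
        corrected=corrected,
        prune_alpha=prune_alpha,
        ridge=ridge,
        max_nodes=max_nodes,
        **options,
    )
    est.fit(data)
    return est.result_


def standard_errors(fit: FitResult, data=None) -> np.ndarray:
    """Edge standard errors of a multivariate fit.

    Recomputed from the inverse observed information of the k-truncated
    likelihood at the fitted parameters when not already stored.
    """
    if fit.se_omega is not None:
        return fit.se_omega
    if data is None:
        raise ValidationError("data required to recompute standard errors")
    if not fit.converged:
        raise ValidationError("standard errors require a converged fit")
    est = MultivariateIsing(
        k=fit.tuning.get("normalizer_k", fit.k), corrected=True
    )
    Xm = _as_matrix(data)
    n, m = Xm.shape
    theta = _pack(fit.tau_hat, fit.omega_hat)
    support = enumerate_support(m, est.k, max_nodes=est.max_nodes)
    T = _suff_stats(support.patterns)
    _, _, cov = est._moments(theta, T)
    iu, ju = _pair_indices(m)
    free = np.concatenate([np.ones(m, dtype=bool), fit.edge_mask[iu, ju]])
    se, _ = est._se_from_cov(cov, free, n, m)
    return se


def prune(fit: FitResult, data, alpha: float = 0.01) -> FitResult:
    """Single Wald prune-then-refit pass on a multivariate fit."""
    est = MultivariateIsing(
        k=fit.k,
        corrected=fit.corrected,
        prune_alpha=alpha,
        ridge=fit.tuning.get("ridge", 0.0),
    )
    est.fit(data)
    return est.result_
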