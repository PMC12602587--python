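"""Nodewise (pseudo-likelihood) estimation of the Ising model.

Each node is regressed logistically on all remaining nodes; the intercept
estimates the node's threshold and the slopes estimate its interaction
weights.  Under selection on a minimum sum score ``k`` the regression must
condition on the selection event: whenever the predictors of a case sum to
``k - 1``, the response is logically forced to 1 (otherwise the case would
not have passed selection), so the case contributes likelihood 1 and is
removed from the fit.  Dropping those rows IS the correction; the
uncorrected baseline is the identical pipeline without the dropping.

Two model-selection flavours are provided:

* :class:`NodewiseIsing` — unpenalised logistic ML with two-sided Wald
  significance thresholding and the AND rule (an edge is kept only if it is
  significant in both of its directed regressions).
* :class:`IsingLasso` — an L1 path per node with extended-BIC model
  selection (the "eLasso" strategy), the AND rule applied to nonzero status.

Symmetrised edge weights are the mean of the two directed slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .errors import (
    DegenerateNodeError,
    ImpossibleConditionError,
    RowBelowCutoffError,
    ValidationError,
)
from .model import IsingModel
from .results import FitResult
from .sampling import BinaryDataset

__all__ = [
    "NodeRegressionData",
    "NodewiseIsing",
    "IsingLasso",
    "prepare_node_regression",
    "corrected_conditional_probability",
    "node_pseudo_log_likelihood",
    "fit_node",
    "fit_pseudolikelihood",
    "fit_elasso",
]

#: absolute slope beyond which a directed logistic fit is treated as separated
SEPARATION_BOUND = 15.0


@dataclass
class NodeRegressionData:
    """Design of one nodewise regression after the selection correction."""

    node: int
    response: np.ndarray
    predictors: np.ndarray
    dropped_rows: np.ndarray
    k: int
    predictor_indices: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.response.shape[0]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, BinaryDataset):
        return data.data
    return BinaryDataset(np.asarray(data)).data


def prepare_node_regression(data, node: int, k: int) -> NodeRegressionData:
    """Build the corrected design for regressing ``node`` on the rest.

    Rows whose predictor sum equals ``k - 1`` are removed (their response is
    logically 1 and they carry likelihood 1); for ``k = 0`` nothing is
    removed.  Rows with total sum below ``k`` are invalid for data claimed
    to be selected at ``k``.
    """
    X = _as_matrix(data)
    n, m = X.shape
    if not 0 <= node < m:
        raise ValidationError(f"node {node} outside [0, {m})")
    sums = X.sum(axis=1)
    below = np.flatnonzero(sums < k)
    if below.size:
        raise RowBelowCutoffError(
            f"row {below[0]} has sum score {sums[below[0]]} < k={k}"
        )
    idx = np.array([j for j in range(m) if j != node])
    predictors = X[:, idx]
    response = X[:, node]
    psums = predictors.sum(axis=1)
    dropped = np.flatnonzero(psums == k - 1) if k >= 1 else np.array([], dtype=int)
    keep = np.ones(n, dtype=bool)
    keep[dropped] = False
    return NodeRegressionData(
        node=node,
        response=response[keep].astype(np.int8),
        predictors=predictors[keep].astype(np.int8),
        dropped_rows=dropped,
        k=k,
        predictor_indices=idx,
    )


def corrected_conditional_probability(
    model: IsingModel, node: int, others, k: int, value: int = 1
) -> float:
    """Pr(y_node = value | remaining nodes, s >= k) under the Ising model.

    When the remaining nodes sum to ``k - 1`` the selection event forces the
    response to 1 (probability exactly 1); at or above ``k`` the selection
    is uninformative and the ordinary logistic value applies; below ``k - 1``
    the conditioning event is impossible.
    """
    others = np.asarray(others)
    if others.shape != (model.m - 1,):
        raise ValidationError(
            f"others must have length m-1={model.m - 1}, got {others.shape}"
        )
    if not np.isin(others, (0, 1)).all():
        raise ValidationError("others entries must be 0 or 1")
    if value not in (0, 1):
        raise ValidationError("value must be 0 or 1")
    s_others = int(others.sum())
    if s_others < k - 1:
        raise ImpossibleConditionError(
            f"predictors sum to {s_others} < k-1={k - 1}: the case could not "
            "have passed selection"
        )
    if s_others == k - 1:
        return 1.0 if value == 1 else 0.0
    idx = np.array([j for j in range(model.m) if j != node])
    eta = model.tau[node] + model.omega[node, idx] @ others
    p1 = float(expit(eta))
    return p1 if value == 1 else 1.0 - p1


def node_pseudo_log_likelihood(
    model: IsingModel, data, node: int, k: int, method: str = "drop"
) -> float:
    """Corrected pseudo-log-likelihood contribution of one node.

    ``method="drop"`` removes rows with predictor sum ``k - 1``;
    ``method="unit"`` keeps them with likelihood 1.  The two are identical.
    """
    X = _as_matrix(data)
    idx = np.array([j for j in range(X.shape[1]) if j != node])
    total = 0.0
    for row in X:
        others = row[idx]
        if k >= 1 and others.sum() == k - 1 and method == "drop":
            continue
        p = corrected_conditional_probability(model, node, others, k, value=row[node])
        total += np.log(p)
    return float(total)


def fit_node(data, node: int, k: int, *, corrected: bool = True):
    """Unpenalised logistic ML for one node on the (corrected) design.

    Returns ``(intercept, slopes, se_slopes, diagnostics)`` where slopes are
    indexed by the remaining nodes in order and diagnostics flags
    separation/non-convergence.
    """
    nd = prepare_node_regression(data, node, k if corrected else 0)
    y = nd.response
    if y.min() == y.max():
        raise DegenerateNodeError(
            [node], f"node {node}: response is constant after correction"
        )
    Xd = sm.add_constant(nd.predictors.astype(float), has_constant="add")
    diagnostics = {"n_dropped": int(nd.dropped_rows.size), "separated": False}
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        converged = bool(res.mle_retvals.get("converged", True))
        llf = float(res.llf)
    except Exception:  # perfect separation or singular design
        converged = False
        params = np.full(Xd.shape[1], np.nan)
        bse = np.full(Xd.shape[1], np.nan)
        llf = np.nan
    if not converged or np.any(np.abs(params[1:]) > SEPARATION_BOUND):
        diagnostics["separated"] = True
        warnings.warn(
            f"node {node}: separation or non-convergence in logistic fit",
            stacklevel=2,
        )
    diagnostics["converged"] = converged
    diagnostics["llf"] = llf
    return float(params[0]), params[1:], bse[1:], diagnostics


def _assemble(
    m, intercepts, directed, included, method, corrected, k, tuning, diagnostics
):
    """Symmetrise directed slopes into a FitResult (mean of the two slopes)."""
    omega = np.zeros((m, m))
    mask = np.zeros((m, m), dtype=bool)
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu, ju):
        if included[i, j] and included[j, i]:
            mask[i, j] = mask[j, i] = True
            w = 0.5 * (directed[i, j] + directed[j, i])
            omega[i, j] = omega[j, i] = w
    return FitResult(
        method=method,
        corrected=corrected,
        k=k,
        tau_hat=np.asarray(intercepts, dtype=float),
        omega_hat=omega,
        edge_mask=mask,
        tuning=tuning,
        converged=all(
            d.get("converged", True) for d in diagnostics["nodes"].values()
        ),
        diagnostics=diagnostics,
    )


class NodewiseIsing(BaseEstimator):
    """Nodewise logistic estimator with Wald thresholding and the AND rule.

    Parameters
    ----------
    k : int, default=0
        Sum-score cutoff the data were selected on.
    corrected : bool, default=True
        Apply the k-1 case-removal correction before each regression.
    alpha : float, default=0.01
        Two-sided Wald significance level for edge inclusion.
    rule : {"and", "or"}, default="and"
        Combine the two directed tests; "and" requires both significant.

    Attributes
    ----------
    tau_, omega_, edge_mask_, converged_, result_ : as in MultivariateIsing.
    """

    def __init__(
        self, k: int = 0, corrected: bool = True, alpha: float = 0.01, rule="and"
    ):
        self.k = k
        self.corrected = corrected
        self.alpha = alpha
        self.rule = rule

    def fit(self, X, y=None):
        from scipy.stats import norm

        Xm = _as_matrix(X)
        n, m = Xm.shape
        if self.rule not in ("and", "or"):
            raise ValidationError("rule must be 'and' or 'or'")
        directed = np.zeros((m, m))
        pvals = np.ones((m, m))
        intercepts = np.zeros(m)
        node_diag = {}
        degenerate = []
        for node in range(m):
            try:
                tau0, slopes, ses, diag = fit_node(
                    Xm, node, self.k, corrected=self.corrected
                )
            except DegenerateNodeError:
                degenerate.append(node)
                continue
            node_diag[node] = diag
            intercepts[node] = tau0
            idx = np.array([j for j in range(m) if j != node])
            directed[node, idx] = np.nan_to_num(slopes)
            if diag["separated"]:
                # conservative: a separated regression certifies no edge
                pvals[node, idx] = 1.0
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    z = slopes / ses
                pvals[node, idx] = np.where(
                    np.isfinite(z), 2 * norm.sf(np.abs(z)), 1.0
                )
        if degenerate:
            raise DegenerateNodeError(degenerate)
        sig = pvals <= self.alpha
        included = sig if self.rule == "and" else (sig | sig.T)
        diagnostics = {
            "nodes": node_diag,
            "directed_pvals": pvals.tolist(),
            "directed_slopes": directed.tolist(),
        }
        result = _assemble(
            m,
            intercepts,
            directed,
            included,
            "nodewise",
            self.corrected,
            self.k,
            {"alpha": self.alpha, "rule": self.rule},
            diagnostics,
        )
        self.n_features_in_ = m
        self.tau_ = result.tau_hat
        self.omega_ = result.omega_hat
        self.edge_mask_ = result.edge_mask
        self.converged_ = result.converged
        self.result_ = result
        return self


def _lasso_path_node(y, Xp, n_lambdas, lambda_min_ratio):
    """L1 logistic path for one node, strongest penalty first.

    Binary predictors admit at most ``2^(m-1)`` distinct design rows, so the
    data are collapsed to weighted unique (pattern, response) rows first; the
    solver cost is then essentially independent of n.
    """
    n = y.shape[0]
    ybar = y.mean()
    lam_max = float(np.max(np.abs(Xp.T @ (y - ybar))) / n)
    lam_max = max(lam_max, 1e-4)
    lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    uniq, counts = np.unique(
        np.hstack([Xp, y[:, None]]), axis=0, return_counts=True
    )
    Xu, yu, w = uniq[:, :-1], uniq[:, -1], counts.astype(float)

    # the empty model is always a candidate (the lam -> inf endpoint); at
    # lam_max itself the solver can return borderline-nonzero coefficients
    icpt0 = float(np.log(ybar / (1.0 - ybar))) if 0 < ybar < 1 else 0.0
    ll0 = float(n * (ybar * icpt0 - np.logaddexp(0.0, icpt0)))
    path = [(np.inf, icpt0, np.zeros(Xp.shape[1]), ll0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in lams:
            clf = LogisticRegression(
                penalty="l1",
                C=1.0 / (n * lam),
                solver="liblinear",
                intercept_scaling=100.0,
                tol=1e-5,
                max_iter=500,
            )
            clf.fit(Xu, yu, sample_weight=w)
            coef = clf.coef_[0].copy()
            icpt = float(clf.intercept_[0])
            eta = icpt + Xu @ coef
            ll = float(np.sum(w * (yu * eta - np.logaddexp(0.0, eta))))
            path.append((lam, icpt, coef, ll))
    return path


def _ebic(ll, d, n, p, gamma):
    return -2.0 * ll + d * np.log(n) + 2.0 * gamma * d * np.log(p)


class IsingLasso(BaseEstimator):
    """Nodewise L1 (eLasso-style) estimator with EBIC model selection.

    Per node, a log-spaced path of L1 penalties is fitted from the smallest
    penalty that zeroes all slopes down to ``lambda_min_ratio`` times it;
    the model minimising EBIC = -2*loglik + d*log(n') + 2*gamma*d*log(m-1)
    is selected, with ``n'`` the post-correction row count and ``d`` the
    number of nonzero slopes.  Edges require nonzero status in both directed
    regressions (AND rule) and are averaged.

    Parameters
    ----------
    k, corrected : as in NodewiseIsing.
    gamma : float, default=0.25
        EBIC hyperparameter; larger values select sparser networks.
    n_lambdas : int, default=100
    lambda_min_ratio : float, default=0.001
    rule : {"and", "or"}, default="and"
    """

    def __init__(
        self,
        k: int = 0,
        corrected: bool = True,
        gamma: float = 0.25,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 0.001,
        rule="and",
    ):
        self.k = k
        self.corrected = corrected
        self.gamma = gamma
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.rule = rule

    def _select_node(self, Xm, node):
        nd = prepare_node_regression(Xm, node, self.k if self.corrected else 0)
        y = nd.response.astype(float)
        if y.min() == y.max():
            raise DegenerateNodeError(
                [node], f"node {node}: response is constant after correction"
            )
        Xp = nd.predictors.astype(float)
        path = _lasso_path_node(y, Xp, self.n_lambdas, self.lambda_min_ratio)
        m1 = Xp.shape[1]
        best = min(
            path,
            key=lambda t: _ebic(
                t[3], int(np.count_nonzero(t[2])), nd.n, m1, self.gamma
            ),
        )
        lam, icpt, coef, ll = best
        return nd, lam, icpt, coef, ll

    def fit(self, X, y=None):
        Xm = _as_matrix(X)
        n, m = Xm.shape
        directed = np.zeros((m, m))
        nonzero = np.zeros((m, m), dtype=bool)
        intercepts = np.zeros(m)
        node_diag = {}
        degenerate = []
        for node in range(m):
            try:
                nd, lam, icpt, coef, ll = self._select_node(Xm, node)
            except DegenerateNodeError:
                degenerate.append(node)
                continue
            intercepts[node] = icpt
            directed[node, nd.predictor_indices] = coef
            nonzero[node, nd.predictor_indices] = coef != 0
            node_diag[node] = {
                "lambda": lam,
                "n_dropped": int(nd.dropped_rows.size),
                "d": int(np.count_nonzero(coef)),
                "llf": ll,
                "converged": True,
            }
        if degenerate:
            raise DegenerateNodeError(degenerate)
        included = nonzero if self.rule == "and" else (nonzero | nonzero.T)
        diagnostics = {"nodes": node_diag}
        result = _assemble(
            m,
            intercepts,
            directed,
            included,
            "elasso",
            self.corrected,
            self.k,
            {
                "gamma": self.gamma,
                "n_lambdas": self.n_lambdas,
                "lambda_min_ratio": self.lambda_min_ratio,
                "rule": self.rule,
            },
            diagnostics,
        )
        self.n_features_in_ = m
        self.tau_ = result.tau_hat
        self.omega_ = result.omega_hat
        self.edge_mask_ = result.edge_mask
        self.converged_ = result.converged
        self.result_ = result
        return self


# -- thin functional wrappers ---------------------------------------------


def fit_pseudolikelihood(
    data, k=None, alpha: float = 0.01, *, corrected: bool = True, rule="and"
) -> FitResult:
    """Nodewise logistic fit with Wald/AND-rule thresholding; see NodewiseIsing."""
    if k is None:
        k = data.cutoff if isinstance(data, BinaryDataset) and data.cutoff else 0
    est = NodewiseIsing(k=k, corrected=corrected, alpha=alpha, rule=rule)
    est.fit(data)
    return est.result_


def fit_elasso(
    data, k=None, gamma: float = 0.25, *, corrected: bool = True, **options
) -> FitResult:
    """Nodewise lasso fit with EBIC selection; see IsingLasso."""
    if k is None:
        k = data.cutoff if isinstance(data, BinaryDataset) and data.cutoff else 0
    est = IsingLasso(k=k, corrected=corrected, gamma=gamma, **options)
    est.fit(data)
    return est.result_
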