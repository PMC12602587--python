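"""Recovery metrics and the factorial simulation harness.

The harness draws post-selection samples from a known "true" network,
fits corrected and uncorrected networks with three estimators
(eLasso, nodewise thresholding, multivariate with pruning), and scores each
fit against the truth with four measures:

* total edge weight error — sum over unordered pairs of |est - true|;
* sensitivity — proportion of true present edges estimated nonzero
  (sign-agnostic);
* specificity — proportion of true absent edges estimated zero;
* proportion of spurious negative edges — negative estimates where the true
  weight is non-negative, out of all unordered pairs (the denominator is
  configurable to true-present pairs only).

The full design is sample sizes {500, 1000, 2500, 5000} x cutoffs {0, 2, 5}
x 100 replicates; each replicate with k > 0 produces six networks
(three estimators x corrected/uncorrected) and three when k = 0, where the
two variants coincide.  Per-replicate seeds are derived deterministically
from (base_seed, n, k, replicate), so results are schedule-invariant and
replicates may run concurrently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError
from .model import IsingModel
from .multivariate import fit_ml
from .nodewise import fit_elasso, fit_pseudolikelihood
from .results import FitResult
from .sampling import sample_truncated

__all__ = [
    "RecoveryMetrics",
    "total_edge_weight_error",
    "sensitivity_specificity",
    "prop_spurious_negative",
    "compute_metrics",
    "design_table",
    "run_study",
    "summarize_study",
    "DEFAULT_SAMPLE_SIZES",
    "DEFAULT_CUTOFFS",
    "DEFAULT_ESTIMATORS",
]

DEFAULT_SAMPLE_SIZES = (500, 1000, 2500, 5000)
DEFAULT_CUTOFFS = (0, 2, 5)
DEFAULT_ESTIMATORS = ("elasso", "nodewise", "multivariate")


@dataclass(frozen=True)
class RecoveryMetrics:
    """The four scalar comparisons between a true and an estimated network."""

    total_edge_weight_error: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    prop_spurious_negative: float


def _true_est(true: IsingModel, est):
    omega_true = true.omega
    if isinstance(est, FitResult):
        omega_est, mask = est.omega_hat, est.edge_mask
    else:
        omega_est = np.asarray(est, dtype=float)
        mask = omega_est != 0
    if omega_est.shape != omega_true.shape:
        raise DimensionMismatchError(
            f"true network is {omega_true.shape}, estimate is {omega_est.shape}"
        )
    iu, ju = np.triu_indices(true.m, k=1)
    return omega_true[iu, ju], omega_est[iu, ju], mask[iu, ju]


def total_edge_weight_error(true: IsingModel, est) -> float:
    """Sum over unordered pairs of |estimated - true| edge weight."""
    wt, we, _ = _true_est(true, est)
    return float(np.abs(we - wt).sum())


def sensitivity_specificity(true: IsingModel, est):
    """(sensitivity, specificity) of edge detection; sign-agnostic.

    Sensitivity is the proportion of true present edges estimated nonzero;
    specificity the proportion of true absent edges estimated zero.  With no
    true present (resp. absent) edges the measure is undefined and returned
    as None rather than 0.
    """
    wt, _, included = _true_est(true, est)
    present = wt != 0
    absent = ~present
    sens = float(included[present].mean()) if present.any() else None
    spec = float((~included[absent]).mean()) if absent.any() else None
    return sens, spec


def prop_spurious_negative(
    true: IsingModel, est, denominator: str = "all_pairs"
) -> float:
    """Proportion of negative estimates where the true weight is >= 0.

    ``denominator`` is ``"all_pairs"`` (default) or ``"present_pairs"``
    (true nonzero edges only).
    """
    wt, we, included = _true_est(true, est)
    spurious = (we < 0) & included & (wt >= 0)
    if denominator == "all_pairs":
        return float(spurious.sum() / wt.size)
    if denominator == "present_pairs":
        present = wt != 0
        return float(spurious[present].sum() / present.sum())
    raise ValueError("denominator must be 'all_pairs' or 'present_pairs'")


def compute_metrics(
    true: IsingModel, est, denominator: str = "all_pairs"
) -> RecoveryMetrics:
    sens, spec = sensitivity_specificity(true, est)
    return RecoveryMetrics(
        total_edge_weight_error=total_edge_weight_error(true, est),
        sensitivity=sens,
        specificity=spec,
        prop_spurious_negative=prop_spurious_negative(true, est, denominator),
    )


# -- the factorial harness -------------------------------------------------


def replicate_seed(base_seed: int, n: int, k: int, replicate: int) -> int:
    """Deterministic, schedule-invariant seed for one replicate (< 2^31)."""
    ss = np.random.SeedSequence([int(base_seed), int(n), int(k), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def design_table(
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    reps: int = 100,
    estimators: Sequence[str] = DEFAULT_ESTIMATORS,
) -> pd.DataFrame:
    """Enumerate the study design: one row per run (n, k, replicate).

    The ``n_networks`` column counts the networks estimated in that run:
    len(estimators) x 2 for k > 0 and len(estimators) for k = 0, where the
    corrected and uncorrected fits coincide.
    """
    rows = [
        {
            "n": n,
            "k": k,
            "replicate": r,
            "n_networks": len(estimators) * (2 if k > 0 else 1),
        }
        for n in sample_sizes
        for k in cutoffs
        for r in range(reps)
    ]
    return pd.DataFrame(rows)


def _fit_one(estimator: str, data, k: int, corrected: bool, alpha, gamma, elasso_opts):
    if estimator == "multivariate":
        return fit_ml(data, k=k, corrected=corrected, prune_alpha=alpha)
    if estimator == "nodewise":
        return fit_pseudolikelihood(data, k=k, alpha=alpha, corrected=corrected)
    if estimator == "elasso":
        return fit_elasso(data, k=k, gamma=gamma, corrected=corrected, **elasso_opts)
    raise ValueError(f"unknown estimator {estimator!r}")


def run_study(
    true: IsingModel,
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    reps: int = 100,
    base_seed: int = 0,
    estimators: Sequence[str] = DEFAULT_ESTIMATORS,
    alpha: float = 0.01,
    gamma: float = 0.25,
    denominator: str = "all_pairs",
    n_jobs: int = 1,
    elasso_opts: Optional[dict] = None,
) -> pd.DataFrame:
    """Run the factorial simulation and return one tidy row per network.

    Columns: condition identifiers (n, k, replicate, estimator, corrected,
    seed), the four recovery metrics, and a failure reason (empty on
    success).  Estimator failures within a replicate are recorded, never
    raised.  Deterministic given ``base_seed``; replicates are independent
    and may run on several workers without changing the output.
    """
    elasso_opts = elasso_opts or {}

    def one_run(n, k, r):
        seed = replicate_seed(base_seed, n, k, r)
        data = sample_truncated(true, n, k, seed)
        out = []
        for estimator in estimators:
            variants = (True,) if k == 0 else (True, False)
            for corrected in variants:
                row = {
                    "n": n,
                    "k": k,
                    "replicate": r,
                    "estimator": estimator,
                    "corrected": corrected,
                    "seed": seed,
                    "total_edge_weight_error": np.nan,
                    "sensitivity": np.nan,
                    "specificity": np.nan,
                    "prop_spurious_negative": np.nan,
                    "failure": "",
                }
                try:
                    fit = _fit_one(
                        estimator, data, k, corrected, alpha, gamma, elasso_opts
                    )
                    mtr = compute_metrics(true, fit, denominator)
                    row.update(
                        total_edge_weight_error=mtr.total_edge_weight_error,
                        sensitivity=mtr.sensitivity,
                        specificity=mtr.specificity,
                        prop_spurious_negative=mtr.prop_spurious_negative,
                    )
                except Exception as exc:  # recorded, not raised
                    row["failure"] = f"{type(exc).__name__}: {exc}"
                out.append(row)
        return out

    runs = [
        (n, k, r) for n in sample_sizes for k in cutoffs for r in range(reps)
    ]
    if n_jobs == 1:
        chunks = [one_run(*run) for run in runs]
    else:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_jobs)(delayed(one_run)(*run) for run in runs)
    return pd.DataFrame([row for chunk in chunks for row in chunk])


def summarize_study(results: pd.DataFrame, statistic: str = "mean") -> pd.DataFrame:
    """Condition-level summary (mean by default, median optionally)."""
    metrics = [
        "total_edge_weight_error",
        "sensitivity",
        "specificity",
        "prop_spurious_negative",
    ]
    grouped = results.groupby(["n", "k", "estimator", "corrected"])[metrics]
    agg = grouped.mean() if statistic == "mean" else grouped.median()
    agg["n_failed"] = results.assign(failed=results["failure"] != "").groupby(
        ["n", "k", "estimator", "corrected"]
    )["failed"].sum()
    return agg.reset_index()


def plot_study(summary: pd.DataFrame, path=None):
    """Metric-vs-n panels per cutoff, corrected dashed vs uncorrected solid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [
        "total_edge_weight_error",
        "sensitivity",
        "specificity",
        "prop_spurious_negative",
    ]
    ks = sorted(summary["k"].unique())
    fig, axes = plt.subplots(
        len(metrics), len(ks), figsize=(3.2 * len(ks), 2.6 * len(metrics)),
        squeeze=False, sharex=True,
    )
    colors = {"elasso": "C0", "nodewise": "C1", "multivariate": "C2"}
    for i, metric in enumerate(metrics):
        for j, k in enumerate(ks):
            ax = axes[i][j]
            sub = summary[summary["k"] == k]
            for (est, corr), grp in sub.groupby(["estimator", "corrected"]):
                grp = grp.sort_values("n")
                ax.plot(
                    grp["n"], grp[metric],
                    linestyle="--" if corr else "-",
                    color=colors.get(est, "k"),
                    label=f"{est} ({'corr' if corr else 'unc'})",
                )
            if i == 0:
                ax.set_title(f"k = {k}")
            if j == 0:
                ax.set_ylabel(metric.replace("_", " "))
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
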