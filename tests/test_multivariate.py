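"""Corrected multivariate ML: likelihood, optimum, standard errors, pruning."""

import numpy as np
import pytest

import isingselect as isl
from isingselect import (
    DegenerateNodeError,
    FitResult,
    IsingModel,
    MultivariateIsing,
    RowBelowCutoffError,
)
from isingselect.multivariate import _pack, _suff_stats
from oracles import brute_neg_log_likelihood, random_model_params


class TestNegLogLikelihood:
    def test_single_row_uniform_truncated_model(self, triple_model):
        data = np.array([[1, 1, 0]])
        assert isl.neg_log_likelihood(triple_model, data, 2) == pytest.approx(
            np.log(4)
        )

    def test_k0_matches_brute_force(self, rng):
        tau, omega = random_model_params(rng, 4)
        model = IsingModel(tau, omega)
        rows = isl.sample_full(model, 50, seed=1).data
        assert isl.neg_log_likelihood(model, rows, 0) == pytest.approx(
            brute_neg_log_likelihood(tau, omega, rows, 0)
        )

    def test_truncated_matches_brute_force(self, rng):
        tau, omega = random_model_params(rng, 5)
        model = IsingModel(tau, omega)
        rows = isl.sample_truncated(model, 40, 2, seed=4).data
        assert isl.neg_log_likelihood(model, rows, 2) == pytest.approx(
            brute_neg_log_likelihood(tau, omega, rows, 2)
        )

    def test_row_below_cutoff_rejected(self, triple_model):
        with pytest.raises(RowBelowCutoffError, match="row 1"):
            isl.neg_log_likelihood(
                triple_model, np.array([[1, 1, 0], [1, 0, 0]]), 2
            )


class TestFitML:
    def test_corrected_flag_irrelevant_at_k0(self, chain_model):
        data = isl.sample_truncated(chain_model, 800, 0, seed=3)
        a = isl.fit_ml(data, k=0, corrected=True)
        b = isl.fit_ml(data, k=0, corrected=False)
        np.testing.assert_allclose(a.omega_hat, b.omega_hat, atol=1e-8)
        np.testing.assert_allclose(a.tau_hat, b.tau_hat, atol=1e-8)

    @pytest.mark.parametrize("k", [0, 2])
    def test_moment_matching_at_optimum(self, chain_model, k):
        """The MLE matches observed and truncated-model moments pairwise."""
        data = isl.sample_truncated(chain_model, 1_500, k, seed=8)
        fit = isl.fit_ml(data, k=k)
        assert fit.converged
        model = IsingModel(fit.tau_hat, fit.omega_hat)
        support = isl.enumerate_support(5, k)
        logp = np.array(
            [np.log(isl.conditional_pmf(model, y, k)) for y in support.patterns]
        )
        T = _suff_stats(support.patterns)
        model_mean = np.exp(logp) @ T
        obs_mean = _suff_stats(data.data).mean(axis=0)
        np.testing.assert_allclose(model_mean, obs_mean, atol=1e-4)

    def test_error_shrinks_with_n(self, chain_model):
        """Consistency: corrected-fit error decreases over a 25x range of n."""
        errs = []
        for n in (400, 10_000):
            per_seed = []
            for seed in range(3):
                data = isl.sample_truncated(chain_model, n, 2, seed=seed)
                fit = isl.fit_ml(data, k=2)
                per_seed.append(isl.total_edge_weight_error(chain_model, fit))
            errs.append(np.mean(per_seed))
        assert errs[1] < errs[0]

    def test_constant_node_rejected(self):
        data = np.array([[1, 0, 1]] * 30)
        with pytest.raises(DegenerateNodeError):
            isl.fit_ml(data, k=0)

    def test_row_below_cutoff_rejected(self):
        data = np.array([[1, 1, 0], [0, 1, 0]])
        with pytest.raises(RowBelowCutoffError):
            isl.fit_ml(data, k=2)


class TestStandardErrors:
    def test_against_finite_difference_hessian(self, rng):
        """Analytic information equals a central-difference Hessian of the NLL."""
        tau, omega = random_model_params(rng, 4, scale=0.5)
        model = IsingModel(tau, omega)
        data = isl.sample_truncated(model, 300, 1, seed=13)
        fit = isl.fit_ml(data, k=1)
        est = MultivariateIsing(k=1)
        support = isl.enumerate_support(4, 1)
        T = _suff_stats(support.patterns)
        theta = _pack(fit.tau_hat, fit.omega_hat)
        _, _, cov = est._moments(theta, T)
        analytic = data.n * cov

        def nll(th):
            t, o = th[:4], np.zeros((4, 4))
            iu, ju = np.triu_indices(4, 1)
            o[iu, ju] = th[4:]
            return isl.neg_log_likelihood(IsingModel(t, o + o.T), data, 1)

        h = 1e-4
        d = theta.size
        fd = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                e_i = np.eye(d)[i] * h
                e_j = np.eye(d)[j] * h
                fd[i, j] = (
                    nll(theta + e_i + e_j)
                    - nll(theta + e_i - e_j)
                    - nll(theta - e_i + e_j)
                    + nll(theta - e_i - e_j)
                ) / (4 * h * h)
        np.testing.assert_allclose(analytic, fd, atol=1e-4 * data.n)

    def test_all_positive(self, chain_model):
        data = isl.sample_truncated(chain_model, 1_000, 0, seed=5)
        fit = isl.fit_ml(data, k=0)
        iu, ju = np.triu_indices(5, 1)
        assert np.all(fit.se_omega[iu, ju] > 0)

    def test_root_n_scaling(self, chain_model):
        ses = []
        for n in (2_000, 8_000):
            data = isl.sample_truncated(chain_model, n, 0, seed=17)
            fit = isl.fit_ml(data, k=0)
            iu, ju = np.triu_indices(5, 1)
            ses.append(np.nanmean(fit.se_omega[iu, ju]))
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.2)

    def test_recompute_from_fit(self, chain_model):
        data = isl.sample_truncated(chain_model, 500, 0, seed=2)
        fit = isl.fit_ml(data, k=0)
        se = isl.standard_errors(fit, data)
        np.testing.assert_allclose(se, fit.se_omega, equal_nan=True)


class TestPrune:
    def test_masked_edges_exactly_zero(self, chain_model):
        data = isl.sample_truncated(chain_model, 400, 0, seed=31)
        fit = isl.fit_ml(data, k=0, prune_alpha=0.01)
        assert np.all(fit.omega_hat[~fit.edge_mask] == 0)
        assert np.array_equal(fit.edge_mask, fit.edge_mask.T)

    def test_no_op_when_all_significant(self, chain_model):
        data = isl.sample_truncated(chain_model, 60_000, 0, seed=41)
        plain = isl.fit_ml(data, k=0)
        pruned = isl.fit_ml(data, k=0, prune_alpha=0.01)
        # with n huge every true chain edge is significant; the pruned refit
        # only removes truly-absent pairs
        iu, ju = np.triu_indices(5, 1)
        true_edges = chain_model.omega[iu, ju] != 0
        assert np.all(pruned.edge_mask[iu, ju][true_edges])
        np.testing.assert_allclose(
            pruned.omega_hat[iu, ju][true_edges],
            plain.omega_hat[iu, ju][true_edges],
            atol=0.05,
        )


class TestFitResultRoundTrip:
    def test_json_lossless(self, chain_model, tmp_path):
        data = isl.sample_truncated(chain_model, 300, 2, seed=7)
        fit = isl.fit_ml(data, k=2, prune_alpha=0.05)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        np.testing.assert_array_equal(back.omega_hat, fit.omega_hat)
        np.testing.assert_array_equal(back.tau_hat, fit.tau_hat)
        np.testing.assert_array_equal(back.edge_mask, fit.edge_mask)
        assert back.method == fit.method
        assert back.k == fit.k
        assert back.corrected == fit.corrected
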