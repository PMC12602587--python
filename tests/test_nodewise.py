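"""Nodewise pseudo-likelihood: the k-1 case removal, Wald/AND and eLasso."""

import numpy as np
import pytest

import isingselect as isl
from isingselect import (
    DegenerateNodeError,
    ImpossibleConditionError,
    IsingLasso,
    IsingModel,
    RowBelowCutoffError,
)
from isingselect.nodewise import _lasso_path_node
from oracles import brute_conditional


class TestPrepareNodeRegression:
    def test_k0_drops_nothing(self, rng):
        data = rng.integers(0, 2, (50, 5))
        nd = isl.prepare_node_regression(data, 0, 0)
        assert nd.dropped_rows.size == 0
        assert nd.n == 50

    def test_forced_response_row_dropped(self):
        # node 0's predictors sum to 2 = k-1 at k=3: the response must be 1
        data = np.array([[1, 1, 1, 0, 0], [1, 1, 1, 1, 0]])
        nd = isl.prepare_node_regression(data, 0, 3)
        assert nd.dropped_rows.tolist() == [0]
        assert data[0, 0] == 1  # the dropped row's response is necessarily 1

    def test_exact_dropped_count(self, rng):
        """Exactly the rows with predictor sum k-1 are dropped, no others."""
        k, node = 3, 0
        rows = []
        # seven rows with predictor sum exactly k-1 (response forced to 1)
        for _ in range(7):
            pred = np.zeros(4, dtype=int)
            pred[rng.choice(4, 2, replace=False)] = 1
            rows.append(np.concatenate([[1], pred]))
        # filler rows with predictor sum >= k
        for _ in range(20):
            pred = np.ones(4, dtype=int)
            pred[rng.integers(0, 4)] = rng.integers(0, 2)
            rows.append(np.concatenate([[rng.integers(0, 2)], pred]))
        data = np.array(rows)
        nd = isl.prepare_node_regression(data, node, k)
        expected = np.flatnonzero(data[:, 1:].sum(axis=1) == k - 1)
        assert nd.dropped_rows.tolist() == expected.tolist()
        assert nd.dropped_rows.size == 7
        assert np.all(nd.predictors.sum(axis=1) >= k)

    def test_row_below_cutoff_rejected(self):
        data = np.array([[0, 1, 0, 0, 0]])
        with pytest.raises(RowBelowCutoffError):
            isl.prepare_node_regression(data, 0, 3)


class TestCorrectedConditionalProbability:
    def test_forced_to_one_at_km1(self, chain_model):
        others = np.array([1, 0, 0, 0])  # sums to k-1 for k=2
        assert isl.corrected_conditional_probability(chain_model, 0, others, 2) == 1.0
        assert (
            isl.corrected_conditional_probability(chain_model, 0, others, 2, value=0)
            == 0.0
        )

    def test_impossible_condition(self, chain_model):
        with pytest.raises(ImpossibleConditionError):
            isl.corrected_conditional_probability(
                chain_model, 0, np.zeros(4, dtype=int), 3
            )

    def test_zero_model_gives_half(self):
        model = IsingModel(np.zeros(4), np.zeros((4, 4)))
        others = np.array([1, 1, 0])
        assert isl.corrected_conditional_probability(model, 1, others, 1) == 0.5

    @pytest.mark.parametrize("k", [0, 2])
    def test_matches_joint_ratio_oracle(self, k, rng):
        """Above the boundary the value is the plain conditional of the joint."""
        m = 4
        tau = rng.normal(0, 1, m)
        omega = np.triu(rng.normal(0, 1, (m, m)), 1)
        model = IsingModel(tau, omega + omega.T)
        node = 2
        for others in ([1, 1, 0], [1, 1, 1], [0, 1, 1]):
            if sum(others) < max(k, 1):
                continue
            y1 = np.insert(others, node, 1)
            y0 = np.insert(others, node, 0)
            num = brute_conditional(tau, omega + omega.T, y1, k)
            den = num + brute_conditional(tau, omega + omega.T, y0, k)
            got = isl.corrected_conditional_probability(
                model, node, np.asarray(others), k
            )
            assert got == pytest.approx(num / den)


class TestCorrectionIdentity:
    def test_drop_equals_unit_likelihood(self, chain_model):
        """Removing forced rows is the same as giving them likelihood one."""
        data = isl.sample_truncated(chain_model, 400, 2, seed=6)
        for node in range(5):
            a = isl.node_pseudo_log_likelihood(chain_model, data, node, 2, "drop")
            b = isl.node_pseudo_log_likelihood(chain_model, data, node, 2, "unit")
            assert a == b  # identical to machine precision


class TestFitNode:
    def test_recovers_chain_weights(self, chain_model):
        data = isl.sample_truncated(chain_model, 50_000, 2, seed=19)
        icpt, slopes, ses, diag = isl.fit_node(data, 0, 2)
        # node 0 interacts only with node 1 (weight 0.5)
        assert slopes[0] == pytest.approx(0.5, abs=0.1)
        assert np.all(np.abs(slopes[1:]) < 0.1)
        assert not diag["separated"]

    def test_null_slopes_within_three_se(self):
        model = IsingModel(np.zeros(4), np.zeros((4, 4)))
        data = isl.sample_full(model, 20_000, seed=23)
        _, slopes, ses, _ = isl.fit_node(data, 1, 0)
        assert np.all(np.abs(slopes) < 3 * ses)

    def test_degenerate_node(self):
        data = np.array([[1, 0, 1], [1, 1, 0], [1, 1, 1]])
        with pytest.raises(DegenerateNodeError):
            isl.fit_node(data, 0, 0)


class TestFitPseudolikelihood:
    def test_structure_and_and_rule(self, chain_model):
        data = isl.sample_truncated(chain_model, 3_000, 0, seed=29)
        fit = isl.fit_pseudolikelihood(data, k=0, alpha=0.01)
        assert np.array_equal(fit.omega_hat, fit.omega_hat.T)
        assert np.all(np.diag(fit.omega_hat) == 0)
        assert np.all(fit.omega_hat[~fit.edge_mask] == 0)
        # AND-rule semantics recoverable from the directed diagnostics
        pv = np.array(fit.diagnostics["directed_pvals"])
        iu, ju = np.triu_indices(5, 1)
        both = (pv[iu, ju] <= 0.01) & (pv[ju, iu] <= 0.01)
        assert np.array_equal(fit.edge_mask[iu, ju], both)
        # symmetrised weight is the mean of the two directed slopes
        sl = np.array(fit.diagnostics["directed_slopes"])
        included = fit.edge_mask[iu, ju]
        np.testing.assert_allclose(
            fit.omega_hat[iu, ju][included],
            0.5 * (sl[iu, ju] + sl[ju, iu])[included],
        )

    def test_corrected_beats_uncorrected_at_k5(self, fixture9):
        errs_c, errs_u = [], []
        for seed in range(10):
            data = isl.sample_truncated(fixture9, 2_000, 5, seed=seed)
            fc = isl.fit_pseudolikelihood(data, k=5, alpha=0.01, corrected=True)
            fu = isl.fit_pseudolikelihood(data, k=5, alpha=0.01, corrected=False)
            errs_c.append(isl.total_edge_weight_error(fixture9, fc))
            errs_u.append(isl.total_edge_weight_error(fixture9, fu))
        assert np.mean(errs_c) < np.mean(errs_u)

    def test_sign_bias_reproduced(self, fixture9):
        """Uncorrected fits on all-positive truth invent more negative edges."""
        neg_c, neg_u = [], []
        for seed in range(10):
            data = isl.sample_truncated(fixture9, 2_000, 5, seed=seed)
            fc = isl.fit_pseudolikelihood(data, k=5, alpha=0.01, corrected=True)
            fu = isl.fit_pseudolikelihood(data, k=5, alpha=0.01, corrected=False)
            neg_c.append(isl.prop_spurious_negative(fixture9, fc))
            neg_u.append(isl.prop_spurious_negative(fixture9, fu))
        assert np.mean(neg_u) > np.mean(neg_c)


class TestIsingLasso:
    def test_path_endpoint_full_shrinkage(self, chain_model):
        data = isl.sample_truncated(chain_model, 500, 0, seed=37)
        nd = isl.prepare_node_regression(data, 0, 0)
        path = _lasso_path_node(
            nd.response.astype(float), nd.predictors.astype(float), 20, 0.001
        )
        lam0, _, coef0, _ = path[0]
        assert np.count_nonzero(coef0) == 0

    def test_gamma_monotonicity(self, chain_model):
        """A larger EBIC gamma never adds edges on the same fitted path."""
        data = isl.sample_truncated(chain_model, 1_000, 0, seed=43)
        lax = IsingLasso(k=0, gamma=0.0, n_lambdas=50).fit(data)
        strict = IsingLasso(k=0, gamma=1.0, n_lambdas=50).fit(data)
        for node in range(5):
            d_lax = lax.result_.diagnostics["nodes"][node]["d"]
            d_strict = strict.result_.diagnostics["nodes"][node]["d"]
            assert d_strict <= d_lax

    def test_null_model_selects_mostly_empty(self):
        model = IsingModel(np.zeros(5), np.zeros((5, 5)))
        empty = 0
        reps = 100
        for seed in range(reps):
            data = isl.sample_full(model, 1_000, seed=seed)
            fit = isl.fit_elasso(data, k=0, n_lambdas=30)
            if not fit.edge_mask.any():
                empty += 1
        assert empty / reps > 0.7

    def test_corrected_beats_uncorrected_at_k5(self, fixture9):
        errs_c, errs_u = [], []
        for seed in range(5):
            data = isl.sample_truncated(fixture9, 2_000, 5, seed=100 + seed)
            fc = isl.fit_elasso(data, k=5, corrected=True, n_lambdas=50)
            fu = isl.fit_elasso(data, k=5, corrected=False, n_lambdas=50)
            errs_c.append(isl.total_edge_weight_error(fixture9, fc))
            errs_u.append(isl.total_edge_weight_error(fixture9, fu))
        assert np.mean(errs_c) < np.mean(errs_u)
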