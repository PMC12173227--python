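import numpy as np
import pytest

from neqbrain.core import CouplingMatrix, LaggedCovariance, SignalPanel
from neqbrain.gec import (
    FitConfig,
    average_lagged_covariances,
    fit_gec,
    fit_group_then_individual,
    fit_objective,
)
from neqbrain.hopf import HopfParams, simulate
from neqbrain.linear_hopf import analytic_lagged_covariance, build_linear_model


def make_params(C, tr=2.0):
    return HopfParams(a=-0.02, omega=0.3, C=C, G=1.0, beta=0.02, tr=tr, dt=0.1)


def analytic_target(C, tr=2.0, lag=1):
    return analytic_lagged_covariance(build_linear_model(make_params(C, tr)), lag * tr, lag)


class TestObjective:
    def test_identity_gives_zero(self, coupling_factory):
        lc = analytic_target(coupling_factory(n=4, asym=0.5))
        assert fit_objective(lc, lc) == 0.0

    def test_single_entry_difference_arithmetic(self):
        # 3 nodes: 6 off-diagonal corr0 entries + 9 lagged entries
        corr0 = np.eye(3)
        lag = np.zeros((3, 3))
        a = LaggedCovariance(corr0=corr0, cov_lag=lag, lag_samples=1)
        lag_b = lag.copy()
        lag_b[0, 1] = 0.1
        b = LaggedCovariance(corr0=corr0, cov_lag=lag_b, lag_samples=1)
        assert fit_objective(a, b) == pytest.approx(0.1**2 / 15, abs=1e-15)

    def test_symmetric_in_arguments(self, coupling_factory):
        x = analytic_target(coupling_factory(n=4, asym=0.3))
        y = analytic_target(coupling_factory(n=4, asym=0.8))
        assert fit_objective(x, y) == pytest.approx(fit_objective(y, x))

    def test_lag_mismatch_rejected(self):
        a = LaggedCovariance(np.eye(2), np.zeros((2, 2)), 1)
        b = LaggedCovariance(np.eye(2), np.zeros((2, 2)), 2)
        with pytest.raises(ValueError, match="lag"):
            fit_objective(a, b)


class TestFit:
    def test_known_truth_is_fixed_point(self, coupling_factory):
        truth = coupling_factory(n=6, density=0.5, asym=0.6)
        target = analytic_target(truth)
        gec, trace = fit_gec(
            target, truth, make_params(truth), FitConfig(max_iter=5)
        )
        assert trace.errors[0] < 1e-12
        assert np.allclose(gec.weights, truth.weights, atol=1e-10)

    def test_recovers_small_network(self, coupling_factory):
        truth = coupling_factory(n=8, density=0.5, asym=0.6)
        target = analytic_target(truth)
        init = truth.with_weights(np.where(truth.mask, 0.05, 0.0))
        gec, trace = fit_gec(
            target, init, make_params(truth),
            FitConfig(max_iter=4000, stall_window=100, stall_tol=1e-7),
        )
        r = np.corrcoef(gec.weights[truth.mask], truth.weights[truth.mask])[0, 1]
        assert r > 0.95
        assert trace.final_error < trace.errors[0]

    def test_error_trace_non_increasing_early(self, coupling_factory):
        truth = coupling_factory(n=8, density=0.5, asym=0.6)
        target = analytic_target(truth)
        init = truth.with_weights(np.where(truth.mask, 0.05, 0.0))
        _, trace = fit_gec(target, init, make_params(truth), FitConfig(max_iter=60))
        assert np.all(np.diff(trace.errors[:50]) <= 0)

    def test_mask_and_bounds_conserved(self, coupling_factory):
        truth = coupling_factory(n=6, density=0.4, asym=0.9)
        target = analytic_target(truth)
        init = truth.with_weights(np.where(truth.mask, 0.01, 0.0))
        cfg = FitConfig(max_iter=200, weight_cap=0.08)
        gec, _ = fit_gec(target, init, make_params(truth), cfg)
        assert np.all(gec.weights[~truth.mask] == 0.0)
        assert np.all(gec.weights >= 0.0)
        assert np.all(gec.weights <= cfg.weight_cap)

    def test_deterministic(self, coupling_factory):
        truth = coupling_factory(n=5, density=0.6, asym=0.4)
        target = analytic_target(truth)
        init = truth.with_weights(np.where(truth.mask, 0.02, 0.0))
        g1, _ = fit_gec(target, init, make_params(truth), FitConfig(max_iter=100))
        g2, _ = fit_gec(target, init, make_params(truth), FitConfig(max_iter=100))
        assert np.array_equal(g1.weights, g2.weights)


class TestGroupThenIndividual:
    def _panels(self, coupling_factory, labels):
        truth = coupling_factory(n=5, density=0.6, asym=0.5)
        panels = []
        for i, label in enumerate(labels):
            params = HopfParams(
                a=-0.02, omega=0.3, C=truth, G=1.0, beta=0.02, tr=2.0,
                dt=0.1, seed=100 + i,
            )
            p = simulate(params, 400, subject_id=f"s{i}", state_label=label)
            panels.append(p)
        return truth, panels

    def test_single_subject_group_continues_descent(self, coupling_factory):
        truth, panels = self._panels(coupling_factory, ["A"])
        sc = truth.with_weights(np.where(truth.mask, 0.02, 0.0))
        cfg = FitConfig(max_iter=300, stall_window=50, stall_tol=1e-6)
        per_subject, per_group = fit_group_then_individual(
            panels, sc, make_params(truth), cfg
        )
        _, trace = per_subject["s0"]
        # the individual fit starts at the group optimum for the same
        # covariances, so it can only continue the descent
        group_target = average_lagged_covariances(
            [analytic_target(per_group["A"])]
        )
        assert trace.final_error <= trace.errors[0] + 1e-15

    def test_identical_subjects_get_identical_gecs(self, coupling_factory):
        truth, panels = self._panels(coupling_factory, ["A"])
        twin = SignalPanel(
            values=panels[0].values.copy(), tr=panels[0].tr,
            subject_id="twin", state_label="A",
        )
        sc = truth.with_weights(np.where(truth.mask, 0.02, 0.0))
        cfg = FitConfig(max_iter=100)
        per_subject, _ = fit_group_then_individual(
            panels + [twin], sc, make_params(truth), cfg
        )
        assert np.array_equal(
            per_subject["s0"][0].weights, per_subject["twin"][0].weights
        )

    def test_empty_average_rejected(self):
        with pytest.raises(ValueError):
            average_lagged_covariances([])

    def test_duplicate_subject_ids_rejected(self, coupling_factory):
        truth, panels = self._panels(coupling_factory, ["A", "A"])
        for p in panels:
            p.subject_id = "same"
        sc = truth.with_weights(np.where(truth.mask, 0.02, 0.0))
        with pytest.raises(ValueError, match="duplicate"):
            fit_group_then_individual(panels, sc, make_params(truth), FitConfig(max_iter=5))
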