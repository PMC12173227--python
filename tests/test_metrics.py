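import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neqbrain.core import SignalPanel
from neqbrain.hopf import HopfParams, simulate
from neqbrain.metrics import asymmetry_count, calibrate_gamma, irreversibility
from neqbrain.stats import spearman_perm


def brute_force_pairs(w, gamma):
    """Independent O(N^2) oracle for the asymmetry count."""
    n = w.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if abs(w[i, j] - w[j, i]) >= gamma:
                count += 1
    return count


class TestAsymmetry:
    def test_symmetric_matrix_counts_zero(self, rng):
        w = rng.random((6, 6))
        w = w + w.T
        assert asymmetry_count(w, 0.001).count == 0

    def test_single_pair_crossing_threshold(self):
        w = np.zeros((3, 3))
        w[0, 1], w[1, 0] = 0.3, 0.1  # gap 0.2
        res = asymmetry_count(w, 0.12)
        assert res.count == 1
        assert res.binarized[0, 1] == res.binarized[1, 0] == 1

    @given(
        w=arrays(np.float64, (90, 90), elements=st.floats(0, 0.2)),
        gamma=st.floats(0.01, 0.2),
    )
    @settings(max_examples=10, deadline=None)
    def test_matches_brute_force_oracle(self, w, gamma):
        assert asymmetry_count(w, gamma).count == brute_force_pairs(w, gamma)

    def test_invariant_under_transposition(self, rng):
        w = rng.random((10, 10)) * 0.2
        assert asymmetry_count(w, 0.05).count == asymmetry_count(w.T, 0.05).count

    def test_binarized_symmetric_zero_diagonal(self, rng):
        res = asymmetry_count(rng.random((8, 8)), 0.1)
        assert np.array_equal(res.binarized, res.binarized.T)
        assert np.all(np.diag(res.binarized) == 0)


class TestCalibrateGamma:
    def test_single_gec_definition(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.30  # max gap 0.30
        assert calibrate_gamma([w]) == pytest.approx(0.30, abs=1e-12)

    def test_minimum_of_maxima(self):
        a = np.zeros((3, 3)); a[0, 1] = 0.30
        b = np.zeros((3, 3)); b[1, 2] = 0.15
        assert calibrate_gamma([a, b]) == pytest.approx(0.15, abs=1e-12)

    def test_grid_property_on_random_cohort(self, rng):
        gecs = [rng.random((10, 10)) * 0.3 for _ in range(5)]
        gamma = calibrate_gamma(gecs)
        # every gEC keeps a nonzero count at gamma ...
        assert all(asymmetry_count(g, gamma).count >= 1 for g in gecs)
        # ... and one grid step higher fails for at least one
        assert any(asymmetry_count(g, gamma + 0.005).count == 0 for g in gecs)

    def test_symmetric_gec_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            calibrate_gamma([np.eye(4)])


class TestIrreversibility:
    def test_nonnegative_and_reversal_invariant(self, noise_panel):
        panel = noise_panel(n=4, t=2000)
        fwd = irreversibility(panel, 1)
        rev = irreversibility(panel.values[:, ::-1], 1)
        assert fwd.value >= 0
        assert fwd.value == rev.value  # construction is reversal-symmetric

    def test_iid_noise_near_zero(self, noise_panel):
        res = irreversibility(noise_panel(n=2, t=10_000), 1)
        assert res.value < 1e-3

    def test_invariant_under_region_permutation(self, noise_panel):
        panel = noise_panel(n=5, t=1500)
        perm = np.array([3, 1, 4, 0, 2])
        assert irreversibility(panel.values, 1).value == pytest.approx(
            irreversibility(panel.values[perm], 1).value, rel=1e-12
        )

    def test_asymmetric_coupling_more_irreversible(self, coupling_factory):
        # the central mechanism: directed (asymmetric) coupling breaks
        # detailed balance, symmetric coupling does not
        sym = coupling_factory(n=10, density=0.4, asym=0.0)
        # same weight sum, fully one-directional pairs
        asym_w = np.where(np.triu(sym.mask), sym.weights + sym.weights.T, 0.0)
        asym = sym.with_weights(asym_w)
        assert asym.weights.sum() == pytest.approx(sym.weights.sum())
        vals = {"sym": [], "asym": []}
        for name, C in (("sym", sym), ("asym", asym)):
            for seed in range(20):
                params = HopfParams(
                    a=-0.02, omega=0.3, C=C, G=1.0, beta=0.02, tr=1.0,
                    dt=0.1, seed=seed,
                )
                vals[name].append(irreversibility(simulate(params, 5000), 1).value)
        assert np.median(vals["asym"]) > np.median(vals["sym"])

    def test_zero_variance_region_rejected(self):
        values = np.vstack([np.zeros(100), np.random.default_rng(1).normal(size=100)])
        with pytest.raises(ValueError, match="zero-variance"):
            irreversibility(values, 1)

    def test_perfect_correlation_rejected(self):
        t = np.arange(100, dtype=float)
        with pytest.raises(ValueError, match="diverges"):
            irreversibility(np.vstack([t, t]), 1)


def test_asymmetry_knob_drives_irreversibility(coupling_factory, rng):
    """Monotone mechanism: gEC asymmetry count correlates positively with
    simulated irreversibility across ground-truth models (Spearman with
    permutation null)."""
    from neqbrain.cohort import generate_mask, generate_ground_truth

    mask = generate_mask(20, 0.3, seed=3)
    counts, irrs = [], []
    for k, kappa in enumerate([0.0, 0.25, 0.5, 1.0]):
        for s in range(5):
            gt = generate_ground_truth(mask, kappa, 0.05, seed=50 + 10 * k + s, tr=2.0)
            counts.append(np.abs(gt.gec.weights - gt.gec.weights.T).sum())
            vals = [
                irreversibility(
                    simulate(
                        dataclasses.replace(gt.params, seed=7000 + 100 * k + 10 * s + r),
                        3000,
                    ),
                    1,
                ).value
                for r in range(10)
            ]
            irrs.append(np.mean(vals))
    res = spearman_perm(counts, irrs, n_perm=2000, seed=0)
    assert res.statistic > 0
    assert res.p_value < 0.05
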