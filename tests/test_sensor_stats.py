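"""Sensor-level statistics: slope t, BH-FDR, cluster permutation, controls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from boundless import sensor_stats, spectral
from boundless.sensor_stats import (
    baseline_correct,
    cluster_perm_test,
    fdr_bh,
    foi_scan,
    order_control,
    order_surrogate,
    percent_signal_change,
    posthoc_pairwise,
    slope_t,
)

from oracles import bh_stepup_reference, exhaustive_cluster_pvalues, ols_slope_t


def _make_ps(power, conditions, blocks=None, freqs=None):
    e = len(conditions)
    power = np.asarray(power, float)
    freqs = np.arange(1.0, 1.0 + power.shape[2]) if freqs is None else freqs
    meta = pd.DataFrame({
        "condition": conditions,
        "block": np.zeros(e, int) if blocks is None else blocks,
        "order_index": np.arange(1, e + 1),
    })
    return spectral.PowerSpectra(power, np.asarray(freqs, float), meta)


class TestSlopeT:
    def test_matches_matrix_ols_oracle(self):
        x = np.array([1, 1, 2, 2, 3, 3], float)
        y = np.array([5, 4, 4, 3, 3, 2], float)
        t, p, df = slope_t(y, x)
        assert df == 4
        assert abs(t - ols_slope_t(y, x)) < 1e-10

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(20):
            x = rng.integers(1, 4, 12).astype(float)
            if len(np.unique(x)) < 2:
                continue
            y = rng.standard_normal(12)
            t, _, _ = slope_t(y, x)
            assert abs(t - ols_slope_t(y, x)) < 1e-10

    def test_constant_y_gives_zero_t_unit_p(self):
        t, p, _ = slope_t(np.full(6, 2.0), np.array([1, 1, 2, 2, 3, 3]))
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        x = np.array([1, 2, 3, 1, 2, 3], float)
        y = rng.standard_normal(6)
        t1, _, _ = slope_t(y, x)
        t2, _, _ = slope_t(-y, x)
        assert t1 == pytest.approx(-t2, abs=1e-12)

    def test_perfect_fit_flagged_degenerate(self):
        t, p, _ = slope_t(np.array([1.0, 1, 2, 2, 3, 3]),
                          np.array([1, 1, 2, 2, 3, 3], float))
        assert np.isinf(t) and p == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            slope_t(np.arange(4.0), np.ones(4))


class TestFdrBH:
    def test_step_up_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        mask = fdr_bh(p, 0.05)
        np.testing.assert_array_equal(mask, [True, True, True, True, False])

    def test_all_ones_rejects_none(self):
        assert not fdr_bh(np.ones(7), 0.05).any()

    def test_single_p_reduces_to_threshold(self):
        assert fdr_bh(np.array([0.04]), 0.05).all()
        assert not fdr_bh(np.array([0.06]), 0.05).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 40) ** 2
        for q in (0.01, 0.05, 0.2):
            ours = fdr_bh(p, q)
            np.testing.assert_array_equal(ours, bh_stepup_reference(p, q))
            from statsmodels.stats.multitest import multipletests

            ref = multipletests(p, alpha=q, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, ref)


def path_graph(n):
    rows = list(range(n - 1))
    cols = list(range(1, n))
    a = sp.csr_matrix((np.ones(n - 1, bool), (rows, cols)), shape=(n, n))
    return a + a.T


class TestClusterPermutation:
    def test_no_suprathreshold_channels_no_clusters(self, rng):
        values = rng.standard_normal((9, 4)) * 1e-3
        values += np.arange(4) * 0.0
        x = np.tile([1, 2, 3], 3).astype(float)
        sm = cluster_perm_test(values, x, path_graph(4), forming_alpha=1e-9,
                               n_perm=200, seed=0)
        assert len(sm.cluster_mass) == 0
        assert (sm.cluster_id == 0).all()

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        """Tiny instance (4-channel path graph, labels 1,1,2,2,3,3): the
        Monte-Carlo cluster p at n_perm=10^4 lies within 3 binomial SDs of
        the exhaustive p over all 90 distinct labelings."""
        x = np.array([1, 1, 2, 2, 3, 3], float)
        values = rng.standard_normal((6, 4))
        values[:, :2] += np.outer(x, [1.0, 0.8])  # a real gradient
        adjacency = path_graph(4)
        import scipy.stats

        threshold = scipy.stats.t.ppf(1 - 0.05 / 2, len(x) - 2)
        masses, p_ex = exhaustive_cluster_pvalues(values, x, adjacency,
                                                  threshold)
        n_perm = 10_000
        sm = cluster_perm_test(values, x, adjacency, forming_alpha=0.05,
                               n_perm=n_perm, seed=1)
        assert len(sm.cluster_mass) == len(masses)
        for p_mc, pe in zip(sm.cluster_p, p_ex):
            sd = np.sqrt(max(pe * (1 - pe), 1e-6) / n_perm)
            assert abs(p_mc - pe) <= 3 * sd + 2 / n_perm

    def test_channel_reordering_invariance(self, rng):
        values = rng.standard_normal((12, 6))
        values[:, 1] += np.tile([1, 2, 3], 4) * 0.8
        x = np.tile([1, 2, 3], 4).astype(float)
        adj = path_graph(6)
        sm1 = cluster_perm_test(values, x, adj, n_perm=300, seed=5)
        perm = rng.permutation(6)
        adj_p = adj[perm][:, perm]
        sm2 = cluster_perm_test(values[:, perm], x, adj_p, n_perm=300, seed=5)
        np.testing.assert_allclose(np.sort(sm1.t), np.sort(sm2.t), rtol=1e-9)
        np.testing.assert_allclose(sorted(sm1.cluster_mass),
                                   sorted(sm2.cluster_mass), rtol=1e-9)

    def test_sign_equivariance(self, rng):
        """Reversing the graded direction flips the recovered slope sign."""
        x = np.tile([1, 2, 3], 6).astype(float)
        noise = rng.standard_normal((18, 4)) * 0.1
        down = noise - np.outer(x, np.ones(4))
        up = noise + np.outer(x, np.ones(4))
        sm_down = cluster_perm_test(down, x, path_graph(4), n_perm=100, seed=0)
        sm_up = cluster_perm_test(up, x, path_graph(4), n_perm=100, seed=0)
        assert (sm_down.t < 0).all() and (sm_up.t > 0).all()

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_perm_test(rng.standard_normal((6, 3)),
                              np.array([1, 1, 2, 2, 3, 3], float),
                              path_graph(3), n_perm=50, seed=0)


class TestFoiScan:
    def test_graded_effect_found_at_target_bins(self, rng):
        e, c, f = 60, 5, 30
        x = np.tile([1, 2, 3], 20).astype(float)
        power = np.exp(rng.standard_normal((e, c, f)) * 0.1)
        power[:, :, 14:18] *= np.exp(-0.5 * x)[:, None, None]
        ps = _make_ps(power, [f"SB{int(v)}" for v in x])
        scan = foi_scan(ps, q=0.05)
        assert scan.foi is not None
        lo, hi = scan.foi
        assert lo <= ps.freqs[14] and hi >= ps.freqs[17]

    def test_all_unit_p_empty_foi(self):
        e = 12
        x = np.tile([1, 2, 3], 4)
        power = np.ones((e, 3, 8))
        ps = _make_ps(power, [f"SB{v}" for v in x])
        scan = foi_scan(ps, q=0.05)
        assert not scan.fdr_mask.any() and scan.foi is None

    def test_longest_run_tie_prefers_lowest(self):
        from boundless.sensor_stats import _longest_true_run

        mask = np.array([True, False, True])
        assert _longest_true_run(mask) == (0, 0)
        assert _longest_true_run(np.array([False, True, True, False, True,
                                           True])) == (1, 2)


class TestOrderControl:
    def test_condition_driven_effect_invisible_to_order_control(self, rng):
        """An effect constant within intervals leaves no temporal-drift
        signature: the order surrogate regression finds no FOI."""
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            x = np.repeat([1, 2, 3, 1, 2, 3], 10).astype(float)
            blocks = np.repeat([0, 1], 30)
            power = np.exp(r.standard_normal((60, 4, 12)) * 0.2)
            power[:, :, 5:8] *= np.exp(-0.7 * x)[:, None, None]
            ps = _make_ps(power, [f"SB{int(v)}" for v in x], blocks=blocks)
            ps.meta["order_index"] = np.tile(np.arange(1, 31), 2)
            scan = order_control(ps, q=0.05)
            hits += scan.foi is None
        assert hits >= 9

    def test_within_block_surrogate_reproduces_condition_code(self):
        x = np.repeat([1, 2, 3], 4)
        ps = _make_ps(np.ones((12, 2, 5)), [f"SB{v}" for v in x])
        ps.meta["order_index"] = np.arange(1, 13)
        surrogate = order_surrogate(ps, mode="within_block")
        np.testing.assert_array_equal(surrogate, x)

    def test_storage_order_invariance(self, rng):
        x = np.repeat([1, 2, 3], 8).astype(float)
        power = np.exp(rng.standard_normal((24, 3, 6)))
        ps = _make_ps(power, [f"SB{int(v)}" for v in x])
        scan1 = order_control(ps)
        perm = rng.permutation(24)
        ps2 = _make_ps(power[perm], [f"SB{int(v)}" for v in x[perm]])
        ps2.meta["order_index"] = ps.meta["order_index"].to_numpy()[perm]
        scan2 = order_control(ps2)
        np.testing.assert_allclose(scan1.t, scan2.t, rtol=1e-9)


class TestPosthocAndPsc:
    def test_identical_distributions_unit_p(self, rng):
        v = rng.standard_normal(60)
        labels = np.tile(["SB1", "SB2", "SB3"], 20)
        tab = posthoc_pairwise(v, labels)
        assert (tab["p_bonferroni"] > 0.3).all()

    def test_bonferroni_is_exactly_3p_capped(self, rng):
        v = rng.standard_normal(30)
        labels = np.tile(["SB1", "SB2", "SB3"], 10)
        tab = posthoc_pairwise(v, labels)
        np.testing.assert_allclose(tab["p_bonferroni"],
                                   np.minimum(1.0, 3 * tab["p"]))

    def test_strong_graded_effect_both_adjacent_contrasts(self, rng):
        x = np.tile([1, 2, 3], 20)
        v = -x + 0.3 * rng.standard_normal(60)
        labels = np.array([f"SB{int(i)}" for i in x])
        tab = posthoc_pairwise(v, labels).set_index("contrast")
        assert tab.loc["SB1 vs SB2", "p_bonferroni"] < 0.05
        assert tab.loc["SB2 vs SB3", "p_bonferroni"] < 0.05

    def test_missing_condition_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            posthoc_pairwise(rng.standard_normal(4),
                             np.array(["SB1", "SB1", "SB2", "SB2"]))

    def test_percent_signal_change_arithmetic(self):
        power = np.ones((6, 2, 3))
        power[3:] *= 0.5  # SB2 epochs at half power
        ps = _make_ps(power, ["SB1"] * 3 + ["SB2"] * 3)
        psc = percent_signal_change(ps, (1, 3), "SB1", "SB2")
        np.testing.assert_allclose(psc, -50.0)
        psc0 = percent_signal_change(ps, (1, 3), "SB1", "SB1")
        np.testing.assert_allclose(psc0, 0.0)

    def test_percent_signal_change_toy_oracle(self):
        # 3 epochs per condition, hand-computed means: a=2, b=3 -> +50%
        power = np.concatenate([np.full((3, 1, 1), 2.0),
                                np.full((3, 1, 1), 3.0)])
        ps = _make_ps(power, ["SB1"] * 3 + ["SB2"] * 3)
        np.testing.assert_allclose(
            percent_signal_change(ps, (1, 1), "SB1", "SB2"), 50.0)


class TestBaselineCorrect:
    def _pair(self, rng, scale=1.0):
        x = np.tile([1, 2, 3], 4)
        blocks = np.repeat([0, 1], 6)
        sb = _make_ps(scale * np.exp(rng.standard_normal((12, 2, 4))),
                      [f"SB{v}" for v in x], blocks=blocks)
        rest = _make_ps(scale * np.exp(rng.standard_normal((6, 2, 4))),
                        ["REST"] * 6, blocks=np.repeat([0, 1], 3))
        return sb, rest

    def test_equal_to_rest_gives_unity(self):
        sb = _make_ps(np.full((6, 2, 3), 4.0), ["SB1", "SB2", "SB3"] * 2)
        rest = _make_ps(np.full((4, 2, 3), 4.0), ["REST"] * 4)
        out = baseline_correct(sb, rest)
        np.testing.assert_allclose(out.power, 1.0)

    def test_global_scaling_invariance(self, rng):
        sb1, rest1 = self._pair(np.random.default_rng(3))
        sb2 = _make_ps(sb1.power * 7.0, sb1.meta["condition"],
                       blocks=sb1.meta["block"].to_numpy())
        rest2 = _make_ps(rest1.power * 7.0, rest1.meta["condition"],
                         blocks=rest1.meta["block"].to_numpy())
        out1 = baseline_correct(sb1, rest1)
        out2 = baseline_correct(sb2, rest2)
        np.testing.assert_allclose(out1.power, out2.power, rtol=1e-12)

    def test_missing_block_rest_rejected(self, rng):
        sb, rest = self._pair(rng)
        rest_b0 = rest.select_epochs(rest.meta["block"].to_numpy() == 0)
        with pytest.raises(ValueError, match="no rest epochs"):
            baseline_correct(sb, rest_b0)
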