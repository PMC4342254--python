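"""Statistical core: BH, dispersion estimation, NB and QB tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import asedivergence as ad
from asedivergence import glm


def _bh_bruteforce(p):
    """Literal step-up definition: adj_i = min over j>=rank(i) of p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * n / (j + 1) for j in range(pos, n)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_hand_worked_examples(self, p, expected):
        np.testing.assert_allclose(ad.bh_adjust(p), expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0),
                    min_size=1, max_size=50))
    def test_matches_bruteforce_stepup(self, p):
        np.testing.assert_allclose(ad.bh_adjust(p), _bh_bruteforce(p),
                                   atol=1e-12)

    def test_nan_propagates_without_entering_ranking(self):
        out = ad.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]],
                                   _bh_bruteforce([0.01, 0.04]))

    def test_adjusted_at_least_raw_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        adj = ad.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestDispersions:
    def _one_way(self, n_per=3, groups=2):
        X = np.zeros((n_per * groups, groups))
        for g in range(groups):
            X[g * n_per:(g + 1) * n_per, g] = 1.0
        return X

    def test_poisson_counts_estimated_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(200, size=(2000, 6))
        disp = ad.estimate_dispersions(y, self._one_way(),
                                       offset=np.zeros(6))
        assert np.median(disp.shrunk) < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        mu, phi = 200.0, 0.1
        lam = rng.gamma(1 / phi, phi * mu, size=(2000, 6))
        y = rng.poisson(lam)
        disp = ad.estimate_dispersions(y, self._one_way(),
                                       offset=np.zeros(6))
        assert 0.07 <= np.median(disp.shrunk) <= 0.13

    def test_shrinkage_limit_pulls_single_gene_to_trend(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(rng.gamma(10, 20, size=(200, 6)))
        weak = ad.estimate_dispersions(y, self._one_way(), prior_df=0.01,
                                       offset=np.zeros(6))
        strong = ad.estimate_dispersions(y, self._one_way(), prior_df=1e5,
                                         offset=np.zeros(6))
        # infinite prior: every estimate collapses onto the local trend
        assert np.abs(np.log(strong.shrunk / strong.trended)).max() < \
            np.abs(np.log(weak.shrunk / weak.trended)).max()
        np.testing.assert_allclose(np.log(strong.shrunk),
                                   np.log(strong.trended), atol=0.3)

    def test_all_zero_gene_rejected(self):
        y = np.ones((10, 6))
        y[3] = 0
        with pytest.raises(ValueError):
            ad.estimate_dispersions(y, self._one_way())


class TestNbGlmTest:
    def test_identical_groups_give_zero_effect_p_one(self):
        y = np.tile([[100, 120, 90, 100, 120, 90]], (5, 1))
        disp = np.full(5, 0.1)
        res = ad.nb_glm_test(y, ["a"] * 3 + ["b"] * 3, np.ones(6), disp)
        np.testing.assert_allclose(res["effect"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_poisson_lrt_oracle_two_by_two(self):
        # dispersion ~ 0, single observation per group: the NB deviance drop
        # equals the closed-form Poisson LRT on a 2x2 layout
        y = np.array([[13.0, 42.0]])
        X_full = np.array([[1.0, 0.0], [1.0, 1.0]])
        X_null = np.ones((2, 1))
        offset = np.log(np.array([100.0, 150.0]))
        phi = np.array([1e-8])
        _, _, dev_full = glm._fit_nb_glm(y, X_full, offset, phi)
        _, _, dev_null = glm._fit_nb_glm(y, X_null, offset, phi)
        lr = dev_null[0] - dev_full[0]
        # Poisson LRT: saturated fit vs pooled-rate fit
        tot = y.sum()
        e = tot * np.exp(offset) / np.exp(offset).sum()
        lr_oracle = 2 * np.sum(y[0] * np.log(y[0] / e))
        assert lr == pytest.approx(lr_oracle, abs=1e-4)

    def test_power_on_large_effect(self):
        rng = np.random.default_rng(5)
        G, phi = 2000, 0.1
        mu = np.full((G, 6), 200.0)
        signal = np.zeros(G, dtype=bool)
        signal[:200] = True
        mu[signal, 3:] *= 4.0  # |log2FC| = 2
        y = rng.poisson(rng.gamma(1 / phi, phi * mu))
        groups = ["a"] * 3 + ["b"] * 3
        X = np.column_stack([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        disp = ad.estimate_dispersions(y, X, offset=np.zeros(6))
        res = ad.nb_glm_test(y, groups, np.ones(6), disp.shrunk)
        assert (res["fdr"][signal] <= 0.05).mean() >= 0.9
        assert (res["effect"][signal].mean()) == pytest.approx(2.0, abs=0.15)

    def test_all_zero_group_flagged_with_bounded_effect(self):
        y = np.array([[0, 0, 0, 50, 60, 55]], dtype=float)
        res = ad.nb_glm_test(y, ["a"] * 3 + ["b"] * 3, np.ones(6),
                             np.array([0.05]))
        assert bool(res["zero_group"].iloc[0])
        assert np.isfinite(res["effect"].iloc[0])


class TestQbRatioTest:
    def _sim(self, rng, p_by_group, totals, n_by_group, G=200, phi=0.05):
        o_cols, s_cols, groups = [], [], []
        for grp, p in p_by_group.items():
            for _ in range(n_by_group[grp]):
                tot = rng.poisson(rng.gamma(1 / phi, phi * totals), size=G)
                o = rng.binomial(tot, p)
                o_cols.append(o)
                s_cols.append(tot - o)
                groups.append(grp)
        return (np.column_stack(o_cols), np.column_stack(s_cols), groups)

    def test_identical_ratios_give_p_one_effect_zero(self):
        o = np.tile([[40, 40, 40, 40]], (3, 1))
        s = np.tile([[60, 60, 60, 60]], (3, 1))
        res = ad.qb_ratio_test(o, s, ["x", "x", "y", "y"])
        np.testing.assert_allclose(res["effect"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        o, s, groups = self._sim(rng, {"F0": 0.7, "F1": 0.5},
                                 400, {"F0": 3, "F1": 6})
        res = ad.qb_ratio_test(o, s, groups)
        res_sw = ad.qb_ratio_test(s, o, groups)
        np.testing.assert_allclose(res["effect"], -res_sw["effect"],
                                   atol=1e-9)
        np.testing.assert_allclose(res["p"], res_sw["p"], atol=1e-12)

    def test_power_four_to_one_versus_balanced(self):
        # F0 at 4:1, F1 at 1:1, ~400 trials per library, 3 vs 6 libraries
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            o, s, groups = self._sim(rng, {"F0": 0.5, "F1": 0.5},
                                     400, {"F0": 3, "F1": 6}, G=400)
            sig, ssig, _ = self._sim(rng, {"F0": 0.8, "F1": 0.5},
                                     400, {"F0": 3, "F1": 6}, G=1)
            o[0], s[0] = sig[0], ssig[0]  # gene 0 carries the signal
            res = ad.qb_ratio_test(o, s, groups)
            hits += bool(res["fdr"].iloc[0] <= 0.05)
        assert hits >= 19

    def test_zero_total_library_dropped(self):
        o = np.array([[10, 0, 12, 9, 11, 10, 10, 12, 9]])
        s = np.array([[10, 0, 8, 11, 9, 10, 10, 8, 11]])
        groups = ["F0"] * 3 + ["F1"] * 6
        res = ad.qb_ratio_test(o, s, groups)
        assert res["n_libraries"].iloc[0] == 8
        assert np.isfinite(res["p"].iloc[0])


class TestJointModel:
    def test_requires_multiple_temperatures(self):
        table = ad.null_dataset(
            ad.SimConfig(n_genes=30, temperatures=("23C",), seed=1))
        with pytest.raises(ValueError):
            ad.joint_temperature_model(table)

    def test_trans_by_temperature_lands_in_ratio_interaction(self):
        c, r, lab = ad.design_regulatory_architecture(
            300, proportions={"trans_only": 0.2}, seed=2)
        r = r * np.array([1.0, 0.0, 0.5, -1.0])
        cfg = ad.SimConfig(n_genes=300, cis=c, trans=r, seed=2,
                           baseline_log2_mean=np.log2(200))
        table, _ = ad.simulate_counts(cfg)
        jm = ad.joint_temperature_model(table)
        trans_genes = np.array([l == "trans_only" for l in lab])
        ratio_hits = (jm["ratio_interaction"]["fdr"] <= 0.05).to_numpy()
        allelic_hits = (jm["allelic_interaction"]["fdr"] <= 0.05).to_numpy()
        assert ratio_hits[trans_genes].mean() >= 0.8
        # a pure trans architecture must not masquerade as cis interaction
        assert allelic_hits.mean() <= 0.05
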