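import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import ultradce as u
from ultradce.errors import InsufficientDataError
from ultradce.stats import gg_five_level
from ultradce.synthetic import CohortSpec, make_cohort, null_cohort


def bruteforce_bh(p, q):
    """Independent step-up oracle: largest k with p_(k) <= qk/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def _single_param_table(values, zones, pirads, ggs, roi_types,
                        parameter="fp"):
    n = len(values)
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "roi_id": [f"R{i}" for i in range(n)],
        "roi_type": roi_types, "zone": zones, "pirads": pirads, "gg": ggs,
        "parameter": parameter, "mean": values, "sd": 0.0, "n_valid": 1,
    })


class TestZoneTtest:
    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        tab = _single_param_table(vals, ["PZ"] * 3 + ["TZ"] * 3,
                                  [1] * 6, ["neg"] * 6, ["normal"] * 6)
        assert u.zone_ttest(tab, "fp") == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        tab = _single_param_table([5.0] * 6, ["PZ"] * 3 + ["TZ"] * 3,
                                  [1] * 6, ["neg"] * 6, ["normal"] * 6)
        assert u.zone_ttest(tab, "fp") == 1.0

    def test_missing_zone_errors(self):
        tab = _single_param_table([1.0, 2.0, 3.0], ["PZ"] * 3, [1] * 3,
                                  ["neg"] * 3, ["normal"] * 3)
        with pytest.raises(InsufficientDataError):
            u.zone_ttest(tab, "fp")

    def test_power_against_large_zone_effect(self):
        # 3-SD zone shift on fp, normal ROIs 29 PZ vs 6 TZ: detected in
        # >= 95% of seeded replicates.
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = CohortSpec(seed=seed, pirads_effects={}, gg_effects={},
                              zone_effects={"fp": 3.0},
                              baselines={"fp": 1.363})
            tab = make_cohort(spec)
            hits += u.zone_ttest(tab, "fp") < 0.05
        assert hits / n_rep >= 0.95


class TestTwowayAnova:
    def test_all_equal_returns_one_with_flag(self):
        tab = _single_param_table(
            [3.0] * 8, ["PZ", "TZ"] * 4, [1, 1, 3, 3, 4, 4, 5, 5],
            ["neg"] * 8, ["normal", "normal"] + ["lesion"] * 6)
        p_zone, p_pirads, flat = u.twoway_anova(tab, "fp")
        assert (p_zone, p_pirads, flat) == (1.0, 1.0, True)

    def test_balanced_design_type2_equals_type1(self):
        # On a balanced 2x4 design the Type II decomposition coincides
        # with sequential (Type I) sums of squares.
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        zones = np.repeat(["PZ", "TZ"], 16)
        pirads = np.tile(np.repeat([1, 3, 4, 5], 4), 2)
        vals = rng.normal(size=32) + 0.5 * (pirads == 5)
        tab = _single_param_table(
            vals, zones, pirads, ["neg"] * 32,
            np.where(pirads == 1, "normal", "lesion"))
        p_zone, p_pirads, _ = u.twoway_anova(tab, "fp")
        df = pd.DataFrame({"value": vals,
                           "zone": pd.Categorical(zones),
                           "pirads": pd.Categorical(pirads)})
        aov1 = sm.stats.anova_lm(
            smf.ols("value ~ C(zone) + C(pirads)", df).fit(), typ=1)
        assert p_zone == pytest.approx(aov1.loc["C(zone)", "PR(>F)"],
                                       abs=1e-10)
        assert p_pirads == pytest.approx(aov1.loc["C(pirads)", "PR(>F)"],
                                         abs=1e-10)

    def test_pure_pirads_effect_selective(self):
        # Strong PI-RADS effect, no zone effect: PI-RADS factor fires,
        # zone p-values stay roughly uniform.
        p_pirads_list, p_zone_list = [], []
        for seed in range(60):
            spec = CohortSpec(seed=seed, gg_effects={}, zone_effects={},
                              pirads_effects={"fp": 1.5},
                              baselines={"fp": 1.363})
            tab = make_cohort(spec)
            pz, pp, _ = u.twoway_anova(tab, "fp")
            p_pirads_list.append(pp)
            p_zone_list.append(pz)
        assert np.mean(np.array(p_pirads_list) < 0.05) >= 0.95
        # zone p should not be systematically small
        assert np.mean(np.array(p_zone_list) < 0.05) <= 0.15


class TestBiopsyTtest:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0] * 2
        tab = _single_param_table(vals, ["PZ"] * 6, [4] * 6,
                                  ["neg"] * 3 + ["2"] * 3, ["lesion"] * 6)
        assert u.biopsy_ttest(tab, "fp") == pytest.approx(1.0)

    def test_power_with_two_sd_effect(self):
        # 2-SD separation between GG-negative and positive PZ lesions.
        rng_power = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            neg = rng.normal(0.0, 1.0, 11)
            pos = rng.normal(2.0, 1.0, 18)
            vals = np.concatenate([neg, pos])
            tab = _single_param_table(
                vals, ["PZ"] * 29, [4] * 29,
                ["neg"] * 11 + ["2"] * 18, ["lesion"] * 29)
            rng_power += u.biopsy_ttest(tab, "fp") < 0.05
        assert rng_power / n_rep > 0.80

    def test_class_absent_errors(self):
        tab = _single_param_table([1.0, 2.0, 3.0], ["PZ"] * 3, [4] * 3,
                                  ["2"] * 3, ["lesion"] * 3)
        with pytest.raises(InsufficientDataError):
            u.biopsy_ttest(tab, "fp")


class TestOnewayGG:
    def test_normals_fold_into_negative_level(self):
        tab = _single_param_table(
            [1.0] * 4, ["PZ"] * 4, [1, 1, 4, 4],
            ["neg", "neg", "neg", "2"],
            ["normal", "normal", "lesion", "lesion"])
        levels = gg_five_level(tab)
        assert list(levels) == ["neg", "neg", "neg", "2"]

    def test_single_level_errors(self):
        tab = _single_param_table([1.0, 2.0, 3.0], ["PZ"] * 3, [1] * 3,
                                  ["neg"] * 3, ["normal"] * 3)
        with pytest.raises(InsufficientDataError):
            u.oneway_anova_gg(tab, "fp")

    def test_monotone_effect_detected(self):
        hits = 0
        for seed in range(50):
            spec = CohortSpec(seed=seed, pirads_effects={}, zone_effects={},
                              gg_effects={"fp": 1.5},
                              baselines={"fp": 1.363})
            tab = make_cohort(spec)
            p, _ = u.oneway_anova_gg(tab, "fp")
            hits += p < 0.001
        assert hits / 50 >= 0.9


class TestTukey:
    def test_two_groups_equal_pooled_ttest(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 9)
        res = u.tukey_hsd(np.concatenate([a, b]),
                          np.array(["a"] * 12 + ["b"] * 9))
        _, p_pooled = sps.ttest_ind(a, b, equal_var=True)
        assert res["p_adj"].iloc[0] == pytest.approx(p_pooled, abs=1e-6)

    def test_only_shifted_group_flagged(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(["g1", "g2", "g3", "g4"], 15)
        vals = rng.normal(0, 1, 60)
        vals[groups == "g4"] += 3.0
        res = u.tukey_hsd(vals, groups)
        involves_g4 = res["group1"].eq("g4") | res["group2"].eq("g4")
        assert res.loc[involves_g4, "reject"].all()
        assert not res.loc[~involves_g4, "reject"].any()

    def test_identical_groups_all_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        res = u.tukey_hsd(vals, groups)
        assert (res["p_adj"] > 0.99).all()


class TestBH:
    def test_small_family_all_flagged(self):
        reject, adj = u.bh_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_flagged(self):
        reject, adj = u.bh_correct([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_p_identity(self):
        reject, adj = u.bh_correct([0.04], q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_bruteforce_stepup_oracle(self, p_values):
        reject, adj = u.bh_correct(p_values, q=0.05)
        np.testing.assert_array_equal(reject,
                                      bruteforce_bh(p_values, 0.05))
        # adjusted p-values are nondecreasing in the raw p ordering
        order = np.argsort(p_values)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_flag_monotonicity_in_p(self):
        p = np.array([0.01, 0.2, 0.04, 0.6])
        rej0, _ = u.bh_correct(p, q=0.05)
        p2 = p.copy()
        p2[1] = 0.001  # lowering one p never unflags another
        rej1, _ = u.bh_correct(p2, q=0.05)
        assert np.all(rej1[rej0])


class TestRunAllStats:
    def test_null_cohort_yields_few_bh_flags(self):
        flagged = 0
        n_rep = 40
        for seed in range(n_rep):
            res = u.run_all_stats(null_cohort(seed=seed), run_tukey=False)
            flagged += res.bh_family["significant"].any()
        # BH at q=0.05 over a null family flags anything in a small
        # fraction of runs only
        assert flagged / n_rep <= 0.15

    def test_family_composition_is_33_tests(self):
        res = u.run_all_stats(null_cohort(seed=1), run_tukey=False)
        assert len(res.bh_family) == 33  # 11 params x 2 factors + 11

    def test_tukey_runs_only_for_significant_parameters(self):
        tab = make_cohort(CohortSpec(seed=5))
        res = u.run_all_stats(tab, run_tukey=True)
        sig = set(res.twoway_table.loc[res.twoway_table["sig_pirads"],
                                       "parameter"])
        assert {k.split(":")[1] for k in res.tukey if k.startswith("pirads:")} \
            == sig
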