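"""Random-effects pooling, heterogeneity, subgroups, outliers, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgcmeta import (
    RandomEffectsMeta,
    estimate_tau2,
    pool_random_effects,
    sensitivity_filter,
    subgroup_analysis,
)
from dgcmeta.simulate import SimulationConfig, simulate_two_arm_studies
from dgcmeta import effects_from_records

from conftest import make_effects

# Independent oracle values for the five-effect fixture, frozen from
# R metafor 4.8-0 (rma with method DL / REML) and a plain lm() fit.
METAFOR_DL = dict(tau2=0.1505128205, est=-3.0888206783, se=0.3415716689,
                  Q=5.3909952607, I2=25.8021978022)
METAFOR_REML = dict(tau2=0.1368661112, est=-3.0908687674, se=0.3374270451)


class TestTau2:
    def test_identical_effects_zero(self):
        es = make_effects([-2.0] * 4, [0.5, 0.4, 0.3, 0.6])
        assert estimate_tau2(es, "DL") == 0.0

    def test_dl_hand_formula(self):
        es = make_effects([-3.0, -4.0, -2.0], [0.5, 0.5, 0.5])
        w = np.array([2.0, 2.0, 2.0])
        mu = np.sum(w * [-3, -4, -2]) / w.sum()
        q = np.sum(w * (np.array([-3.0, -4.0, -2.0]) - mu) ** 2)
        c = w.sum() - np.sum(w**2) / w.sum()
        expected = max(0.0, (q - 2) / c)
        assert estimate_tau2(es, "DL") == pytest.approx(expected, rel=1e-12)

    def test_matches_cross_package_oracle(self, tiny_effects):
        assert estimate_tau2(tiny_effects, "DL") == pytest.approx(
            METAFOR_DL["tau2"], rel=1e-8)
        assert estimate_tau2(tiny_effects, "REML") == pytest.approx(
            METAFOR_REML["tau2"], rel=1e-5)

    def test_reml_recovers_simulated_truth(self, rng):
        true_tau2, v_i = 0.5, 0.2
        y = rng.normal(-3.0, np.sqrt(true_tau2 + v_i), size=200)
        es = make_effects(y, [v_i] * 200)
        est = estimate_tau2(es, "REML")
        # sampling SD of tau2-hat approx sqrt(2/k)*(v+tau2)
        assert abs(est - true_tau2) < 3 * np.sqrt(2 / 200) * (v_i + true_tau2)

    def test_dl_reml_agree_when_well_conditioned(self, rng):
        y = rng.normal(0.5, np.sqrt(0.3 + 0.2), size=100)
        es = make_effects(y, [0.2] * 100)
        dl, reml = estimate_tau2(es, "DL"), estimate_tau2(es, "REML")
        assert dl == pytest.approx(reml, rel=0.10)

    def test_requires_two_effects(self):
        with pytest.raises(ValueError):
            estimate_tau2(make_effects([-3.0], [0.25]), "DL")


class TestPooling:
    def test_single_effect_pass_through(self):
        with pytest.warns(UserWarning, match="single effect"):
            r = pool_random_effects(make_effects([-3.0], [0.25]))
        assert r.estimate == -3.0
        assert r.se == pytest.approx(0.5)
        assert r.I2 == 0.0

    def test_zero_tau2_reduces_to_fixed_effect(self):
        es = make_effects([-2.0] * 4, [0.5, 0.4, 0.3, 0.6])
        r = pool_random_effects(es, "DL")
        w = 1.0 / np.array([0.5, 0.4, 0.3, 0.6])
        assert r.tau2 == 0.0
        assert r.estimate == pytest.approx(-2.0)
        assert r.se == pytest.approx(1 / np.sqrt(w.sum()))

    def test_matches_cross_package_oracle(self, tiny_effects):
        model = RandomEffectsMeta(tiny_effects)
        dl = model.fit("DL")
        assert dl.estimate == pytest.approx(METAFOR_DL["est"], rel=1e-9)
        assert dl.se == pytest.approx(METAFOR_DL["se"], rel=1e-9)
        assert dl.Q == pytest.approx(METAFOR_DL["Q"], rel=1e-9)
        assert dl.I2 == pytest.approx(METAFOR_DL["I2"], rel=1e-8)
        reml = model.fit("REML")
        assert reml.estimate == pytest.approx(METAFOR_REML["est"], rel=1e-6)
        assert reml.se == pytest.approx(METAFOR_REML["se"], rel=1e-6)

    def test_ci_uses_normal_quantile(self, tiny_effects):
        r = RandomEffectsMeta(tiny_effects).fit("DL")
        assert r.ci_half_width == pytest.approx(1.959963984540054 * r.se)

    def test_mixed_families_rejected(self):
        es = (make_effects([1.0], [0.2], tag="hedges_g")
              + make_effects([5.0], [0.2], tag="percent_per_degC"))
        with pytest.raises(ValueError, match="mixed"):
            RandomEffectsMeta(es)

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.05, 2.0)),
                    min_size=2, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_estimate_within_effect_range(self, pairs):
        ys = [p[0] for p in pairs]
        vs = [p[1] for p in pairs]
        r = pool_random_effects(make_effects(ys, vs), "DL")
        assert min(ys) - 1e-9 <= r.estimate <= max(ys) + 1e-9
        assert r.tau2 >= 0.0
        assert 0.0 <= r.I2 <= 100.0

    def test_se_shrinks_with_more_effects(self):
        prev = np.inf
        for k in (3, 6, 12, 24):
            r = pool_random_effects(make_effects([-2.0] * k, [0.4] * k), "DL")
            assert r.se < prev
            prev = r.se

    def test_i2_zero_when_q_below_df(self):
        es = make_effects([-2.0, -2.01, -1.99], [1.0, 1.0, 1.0])
        r = pool_random_effects(es, "DL")
        assert r.Q <= r.df
        assert r.I2 == 0.0
        assert r.tau2 == 0.0

    def test_summary_mentions_key_quantities(self, tiny_effects):
        text = RandomEffectsMeta(tiny_effects).fit("DL").summary()
        for token in ("tau^2", "I^2", "95% CI", "estimate"):
            assert token in text


class TestSubgroups:
    def test_degenerate_partition_equals_overall(self, tiny_effects):
        sub = subgroup_analysis(tiny_effects, ["all"] * 5, "DL")
        assert sub.per_subgroup["all"].estimate == pytest.approx(sub.overall.estimate)
        assert sum(r.k for r in sub.per_subgroup.values()) == sub.overall.k

    def test_disjoint_truths_recovered(self, rng):
        kA, kB = 40, 40
        yA = rng.normal(-3.0, np.sqrt(0.2), kA)
        yB = rng.normal(2.0, np.sqrt(0.2), kB)
        es = make_effects(np.concatenate([yA, yB]), [0.2] * (kA + kB),
                          orders=["A"] * kA + ["B"] * kB)
        sub = subgroup_analysis(es, method="DL")
        assert sub.per_subgroup["A"].estimate == pytest.approx(-3.0, abs=0.35)
        assert sub.per_subgroup["B"].estimate == pytest.approx(2.0, abs=0.35)
        # subgroup tau² are estimated separately
        assert set(sub.per_subgroup) == {"A", "B"}

    def test_unlabeled_effect_rejected(self, tiny_effects):
        with pytest.raises(ValueError, match="label"):
            subgroup_analysis(tiny_effects, ["A", "", "B", "A", "B"])


class TestOutliers:
    def test_homogeneous_set_unflagged(self, rng):
        # spread well below the sampling SD, so no residual can look extreme
        y = rng.normal(-2.0, np.sqrt(0.05), 20)
        es = make_effects(y, [0.3] * 20)
        res = RandomEffectsMeta(es).detect_outliers(method="DL")
        assert not res.flags.any()
        assert res.refit.k == 20

    def test_planted_outlier_flagged(self, rng):
        y = list(rng.normal(-2.0, 0.1, 19)) + [-2.0 + 10 * np.sqrt(0.3)]
        es = make_effects(y, [0.3] * 20)
        res = RandomEffectsMeta(es).detect_outliers(method="DL")
        assert res.flags[-1]
        assert res.flags.sum() == 1
        assert res.removed_ids == ("s019",)
        assert res.refit.k == 19

    def test_needs_three_effects(self):
        with pytest.raises(ValueError):
            RandomEffectsMeta(make_effects([-1.0, 1.0], [0.2, 0.2])).detect_outliers()


class TestSensitivityFilter:
    def test_all_positive_identity(self):
        es = make_effects([5.0, 7.0], [1.0, 1.0], tag="percent_per_degC")
        assert sensitivity_filter(es) == es

    def test_negative_values_removed(self):
        es = make_effects([5.0, -1.0, 7.0, -0.5], [1.0] * 4,
                          tag="percent_per_degC")
        with pytest.warns(UserWarning, match="removed 2"):
            kept = sensitivity_filter(es)
        assert [e.value for e in kept] == [5.0, 7.0]

    def test_wrong_family_rejected(self):
        es = make_effects([5.0, -1.0], [1.0, 1.0], tag="hedges_g")
        with pytest.raises(ValueError):
            sensitivity_filter(es)

    def test_filter_shifts_pool_upward(self, rng):
        y = rng.normal(6.0, 3.0, 40)
        es = make_effects(y, [1.0] * 40, tag="percent_per_degC")
        before = pool_random_effects(es, "DL").estimate
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            kept = sensitivity_filter(es)
        if len(kept) < len(es):
            after = pool_random_effects(kept, "DL").estimate
            assert after > before


class TestClosedLoopRecovery:
    def test_two_arm_generator_recovers_truth(self):
        cfg = SimulationConfig(seed=77, objective="hygric", k_studies=200,
                               true_effect=-3.0, tau2=0.5,
                               taxonomy_shape=(3, 2, 3))
        es = effects_from_records(simulate_two_arm_studies(cfg))
        r = pool_random_effects(es, "REML")
        assert r.estimate == pytest.approx(-3.0, abs=3 * r.se)
        assert r.tau2 == pytest.approx(0.5, abs=0.35)
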