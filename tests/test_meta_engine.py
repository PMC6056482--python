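import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snpmeta.genetic_models import FourfoldTable, StudyEffect, Z975, study_effect
from snpmeta.meta_engine import (
    UndefinedPoolError,
    choose_model,
    cochran_q,
    dl_tau_squared,
    i_squared,
    meta_analyze,
    pool_fixed_mh,
    pool_random_dl,
)


def eff(log_or, se, sid="s", model="allele"):
    return StudyEffect(study_id=sid, model=model, log_or=log_or, se=se,
                       or_value=math.exp(log_or),
                       ci_low=math.exp(log_or - Z975 * se),
                       ci_high=math.exp(log_or + Z975 * se), p_value=1.0)


class TestHeterogeneity:
    def test_identical_effects_give_zero_q(self):
        q, df, p = cochran_q([eff(0.2, 0.1, "a"), eff(0.2, 0.1, "b")])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_hand_computed_q(self):
        # w = 100 each, theta_hat = 0.25, Q = 100*(0.25^2)*2 = 12.5
        q, df, p = cochran_q([eff(0.0, 0.1), eff(0.5, 0.1)])
        assert q == pytest.approx(12.5, abs=1e-10)

    def test_single_study_q_undefined(self):
        assert cochran_q([eff(0.1, 0.2)]) == (0.0, 0, 1.0)

    @pytest.mark.parametrize("Q,k,expected", [(10, 10, 10.0), (5, 10, 0.0),
                                              (40, 11, 75.0), (0, 5, 0.0)])
    def test_i_squared(self, Q, k, expected):
        assert i_squared(Q, k) == pytest.approx(expected)

    def test_q_brute_force_oracle(self, toy_effects):
        w = [1 / e.se**2 for e in toy_effects]
        th = [e.log_or for e in toy_effects]
        that = sum(wi * ti for wi, ti in zip(w, th)) / sum(w)
        q_direct = sum(wi * (ti - that) ** 2 for wi, ti in zip(w, th))
        q, _, _ = cochran_q(toy_effects)
        assert q == pytest.approx(q_direct, abs=1e-10)


class TestMantelHaenszel:
    def test_single_table_reduces_to_crude_or_and_woolf_ci(self):
        t = FourfoldTable(20, 80, 10, 90, model="allele", study_id="only")
        pooled = pool_fixed_mh([t])
        single = study_effect(t)
        assert pooled.pooled_or == pytest.approx(2.25, abs=1e-12)
        assert pooled.ci_low == pytest.approx(single.ci_low, abs=1e-10)
        assert pooled.ci_high == pytest.approx(single.ci_high, abs=1e-10)

    def test_mirror_symmetry_pools_to_one(self):
        t1 = FourfoldTable(20, 80, 10, 90, model="allele", study_id="a")
        t2 = FourfoldTable(10, 90, 20, 80, model="allele", study_id="b")
        assert pool_fixed_mh([t1, t2]).pooled_or == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_small_tables(self):
        cells = [(4, 6, 3, 7), (2, 8, 5, 5), (6, 4, 4, 6)]
        tabs = [FourfoldTable(*c, model="allele", study_id=f"t{i}")
                for i, c in enumerate(cells)]
        R = sum(a * d / (a + b + c + d) for a, b, c, d in cells)
        S = sum(b * c / (a + b + c + d) for a, b, c, d in cells)
        assert pool_fixed_mh(tabs).pooled_or == pytest.approx(R / S, abs=1e-12)

    def test_empty_margin_rejected(self):
        t = FourfoldTable(0, 10, 0, 10, model="allele")
        with pytest.raises(UndefinedPoolError):
            pool_fixed_mh([t])

    def test_agrees_with_ivw_on_homogeneous_large_counts(self):
        rng = np.random.default_rng(4)
        tabs = []
        for i in range(10):
            n = int(rng.integers(2000, 4000))
            c_exp = int(rng.integers(800, 1200))
            # common OR = 1.5
            a = int(round(c_exp * 1.5 / (1 + 0.5 * c_exp / n) ))
            tabs.append(FourfoldTable(a, n - a, c_exp, n - c_exp,
                                      model="allele", study_id=f"h{i}"))
        effs = [study_effect(t) for t in tabs]
        w = np.array([1 / e.se**2 for e in effs])
        ivw = float((w * np.array([e.log_or for e in effs])).sum() / w.sum())
        mh = math.log(pool_fixed_mh(tabs).pooled_or)
        assert abs(mh - ivw) < 0.01


class TestRandomEffects:
    def test_hand_computed_tau_squared(self):
        # Q = 12.5, df = 1, sum w = 200, sum w^2 / sum w = 100
        effects = [eff(0.0, 0.1), eff(0.5, 0.1)]
        assert dl_tau_squared(effects) == pytest.approx(0.115, abs=1e-10)
        pooled = pool_random_dl(effects)
        assert math.log(pooled.pooled_or) == pytest.approx(0.25, abs=1e-10)

    def test_homogeneous_truncates_to_fixed_ivw(self):
        effects = [eff(0.2, 0.1, "a"), eff(0.2, 0.2, "b"), eff(0.2, 0.15, "c")]
        assert dl_tau_squared(effects) == 0.0
        pooled = pool_random_dl(effects)
        w = [1 / e.se**2 for e in effects]
        ivw = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
        assert math.log(pooled.pooled_or) == pytest.approx(ivw, abs=1e-12)

    def test_equal_se_limit_is_arithmetic_mean(self):
        effects = [eff(x, 0.2, f"e{i}") for i, x in enumerate([0.1, 0.4, 0.7])]
        pooled = pool_random_dl(effects)
        assert math.log(pooled.pooled_or) == pytest.approx(0.4, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(-1.5, 1.5), st.floats(0.05, 0.8)),
                    min_size=2, max_size=12))
    def test_random_ci_never_narrower_than_fixed(self, pairs):
        effects = [eff(lo, se, f"e{i}") for i, (lo, se) in enumerate(pairs)]
        re_res = pool_random_dl(effects)
        w = np.array([1 / e.se**2 for e in effects])
        fixed_width = 2 * Z975 / math.sqrt(w.sum())
        re_width = math.log(re_res.ci_high) - math.log(re_res.ci_low)
        assert re_width >= fixed_width - 1e-9
        assert re_res.tau_squared >= 0.0


class TestModelChoice:
    @pytest.mark.parametrize(
        "i2,p_q,expected",
        [(70.5, 0.0002, "random_DL"), (9.9, 0.2764, "fixed_MH"),
         (60.0, 0.05, "fixed_MH"), (40.0, 0.001, "fixed_MH")],
    )
    def test_conjunction_rule(self, i2, p_q, expected):
        # reconstruct (Q, k) giving the requested I2: I2 = (Q - (k-1))/Q*100
        k = 10
        Q = (k - 1) / (1 - i2 / 100.0)
        assert i_squared(Q, k) == pytest.approx(i2, abs=1e-9)
        assert choose_model(Q, k, p_q) == expected


class TestMetaAnalyze:
    def test_two_identical_studies(self):
        t = FourfoldTable(20, 80, 10, 90, model="allele", study_id="a")
        t2 = FourfoldTable(20, 80, 10, 90, model="allele", study_id="b")
        r = meta_analyze([t, t2])
        assert r.pooled_or == pytest.approx(2.25, abs=1e-12)
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.effect_model == "fixed_MH"

    def test_zero_cells_handled_via_continuity(self):
        t = FourfoldTable(0, 100, 8, 92, model="recessive", study_id="z")
        t2 = FourfoldTable(5, 95, 6, 94, model="recessive", study_id="y")
        r = meta_analyze([t, t2])
        assert r.k == 2 and r.pooled_or > 0


class TestAgainstReferenceImplementation:
    """Frozen values computed once with an independent R reference
    implementation (metafor: rma.mh, escalc + rma(method='DL')) on the
    five-study toy set."""

    def test_mh(self, toy_tables):
        r = pool_fixed_mh(toy_tables)
        assert r.pooled_or == pytest.approx(1.165796186080, abs=1e-9)
        assert r.ci_low == pytest.approx(0.862447205239, abs=1e-6)
        assert r.ci_high == pytest.approx(1.575842253560, abs=1e-6)

    def test_dl(self, toy_effects):
        r = pool_random_dl(toy_effects)
        assert r.pooled_or == pytest.approx(1.125992365936, abs=1e-9)
        assert r.ci_low == pytest.approx(0.679309907656, abs=1e-6)
        assert r.ci_high == pytest.approx(1.866392340017, abs=1e-6)
        assert r.tau_squared == pytest.approx(0.202348193301, abs=1e-9)

    def test_heterogeneity(self, toy_effects):
        q, df, p = cochran_q(toy_effects)
        assert q == pytest.approx(10.415465926521, abs=1e-9)
        assert p == pytest.approx(0.033981561977, abs=1e-9)
        assert i_squared(q, 5) == pytest.approx(61.595573081231, abs=1e-8)
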