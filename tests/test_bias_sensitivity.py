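import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from snpmeta.bias_sensitivity import (
    InsufficientStudiesError,
    begg_test,
    egger_test,
    funnel_data,
    leave_one_out,
)
from snpmeta.genetic_models import FourfoldTable
from test_meta_engine import eff


class TestEgger:
    def test_effects_proportional_to_precision_give_zero_intercept(self):
        # theta_i identical: standardized effects lie exactly on a line
        # through the origin, so the intercept estimate is exactly 0
        effects = [eff(0.3, se, f"e{i}") for i, se in
                   enumerate([0.1, 0.2, 0.3, 0.4])]
        r = egger_test(effects)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_closed_form_ols_oracle(self):
        data = [(0.2, 0.1), (0.3, 0.2), (0.5, 0.4), (0.1, 0.05)]
        effects = [eff(t, s, f"e{i}") for i, (t, s) in enumerate(data)]
        r = egger_test(effects)
        # independent oracle: statsmodels OLS of theta/se on 1/se
        import statsmodels.api as sm
        x = np.array([1 / s for _, s in data])
        y = np.array([t / s for t, s in data])
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert r.statistic == pytest.approx(fit.tvalues[0], abs=1e-10)
        assert r.p_value == pytest.approx(fit.pvalues[0], abs=1e-10)

    def test_matches_reference_implementation(self, toy_effects):
        # frozen from R metafor regtest(model="lm", predictor="sei")
        r = egger_test(toy_effects)
        assert r.statistic == pytest.approx(-0.613172059217, abs=1e-9)
        assert r.p_value == pytest.approx(0.583118505952, abs=1e-9)

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([eff(0.1, 0.1), eff(0.2, 0.2)])

    def test_identical_precisions_degenerate(self):
        with pytest.raises(ValueError):
            egger_test([eff(0.1, 0.2, "a"), eff(0.2, 0.2, "b"),
                        eff(0.3, 0.2, "c")])


class TestBegg:
    def test_identical_effects_score_zero(self):
        effects = [eff(0.25, se, f"e{i}") for i, se in
                   enumerate([0.1, 0.2, 0.3])]
        r = begg_test(effects)
        assert r.kendall_score == 0
        assert r.p_value == pytest.approx(1.0)

    def test_score_matches_kendalltau_oracle(self):
        data = [(0.05, 0.08), (0.31, 0.2), (-0.22, 0.12), (0.55, 0.4),
                (0.18, 0.25)]
        effects = [eff(t, s, f"e{i}") for i, (t, s) in enumerate(data)]
        r = begg_test(effects)
        # reconstruct the deviates exactly as the method defines them,
        # then get the Kendall score from scipy as the oracle
        se2 = np.array([s**2 for _, s in data])
        th = np.array([t for t, _ in data])
        w = 1 / se2
        u = (th - (w * th).sum() / w.sum()) / np.sqrt(se2 - 1 / w.sum())
        tau = stats.kendalltau(u, se2).statistic
        k = len(data)
        assert r.kendall_score == pytest.approx(tau * k * (k - 1) / 2, abs=1e-9)
        # continuity-corrected normal approximation, recomputed directly
        z = (abs(r.kendall_score) - 1) / math.sqrt(k * (k - 1) * (2 * k + 5) / 18)
        assert r.p_value == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)

    def test_sign_flip_invariance(self, toy_effects):
        flipped = [dataclasses.replace(e, log_or=-e.log_or) for e in toy_effects]
        assert begg_test(toy_effects).p_value == pytest.approx(
            begg_test(flipped).p_value, abs=1e-12)

    def test_needs_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            begg_test([eff(0.1, 0.1), eff(0.2, 0.2)])


class TestFunnel:
    def test_single_study_centered_on_its_effect(self):
        e = eff(0.4, 0.2, "solo")
        f = funnel_data([e])
        assert f["log_or"] == [pytest.approx(0.4)]
        assert f["pooled_log_or"] == pytest.approx(0.4)
        assert f["boundary_low"][0] == pytest.approx(0.4)  # SE=0 apex

    def test_point_count_and_boundary_shape(self, toy_effects):
        f = funnel_data(toy_effects)
        assert len(f["log_or"]) == 5
        lo, hi = np.array(f["boundary_low"]), np.array(f["boundary_high"])
        assert np.all(hi >= lo)

    def test_coverage_on_unbiased_effects(self):
        # effects drawn at their own SE should fall within the pseudo-95%
        # funnel about 95% of the time
        rng = np.random.default_rng(12)
        n, hits = 2000, 0
        mu = 0.1
        ses = rng.uniform(0.05, 0.5, n)
        thetas = rng.normal(mu, ses)
        w = 1 / ses**2
        pooled = (w * thetas).sum() / w.sum()
        half = 1.959964 * ses
        hits = np.sum(np.abs(thetas - pooled) <= half)
        assert 0.93 < hits / n < 0.97


class TestLeaveOneOut:
    def _tables(self, cells):
        return [FourfoldTable(*c, model="allele", study_id=f"t{i}")
                for i, c in enumerate(cells)]

    def test_identical_studies_leave_reference_unchanged(self):
        tabs = self._tables([(20, 80, 10, 90)] * 4)
        sens = leave_one_out(tabs)
        for _, r in sens.refits:
            assert r.pooled_or == pytest.approx(sens.reference.pooled_or,
                                                abs=1e-12)
        assert sens.influential() == []

    def test_duplicated_study_either_copy_equivalent(self, toy_tables):
        tabs = toy_tables + [dataclasses.replace(toy_tables[0], study_id="dup")]
        sens = leave_one_out(tabs)
        by_id = dict(sens.refits)
        assert by_id["s0"].pooled_or == pytest.approx(
            by_id["dup"].pooled_or, abs=1e-12)

    def test_two_studies_each_refit_is_other_crude_or(self):
        tabs = self._tables([(20, 80, 10, 90), (40, 80, 25, 95)])
        sens = leave_one_out(tabs)
        by_id = dict(sens.refits)
        assert by_id["t0"].pooled_or == pytest.approx(1.9, abs=1e-12)
        assert by_id["t1"].pooled_or == pytest.approx(2.25, abs=1e-12)

    def test_refit_count_and_size(self, toy_tables):
        sens = leave_one_out(toy_tables)
        assert len(sens.refits) == 5
        assert all(r.k == 4 for _, r in sens.refits)

    def test_needs_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(self._tables([(20, 80, 10, 90)]))
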