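import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from cernaforge.cerna import CeRNAPair
from cernaforge.io_formats import ExpressionMatrix
from cernaforge.survival import (
    cox_regression,
    km_median_split_screen,
    logrank_test,
    prune_network,
)

from conftest import make_clinical


class TestLogrank:
    def test_identical_arms_give_null_result(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_arms_match_reference_fixture(self):
        ta, ea = np.array([1.0, 2.0, 3.0]), np.ones(3, int)
        tb, eb = np.array([4.0, 5.0, 6.0]), np.ones(3, int)
        chi2, p = logrank_test(ta, ea, tb, eb)
        ref = lifelines_logrank(ta, tb, ea, eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_matches_reference_on_random_cohorts_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(8, 30))
            ta = rng.integers(1, 10, n).astype(float)  # integer times force ties
            tb = rng.integers(1, 10, n).astype(float)
            ea = rng.integers(0, 2, n)
            eb = rng.integers(0, 2, n)
            if ea.sum() == 0 or eb.sum() == 0:
                continue
            chi2, p = logrank_test(ta, ea, tb, eb)
            ref = lifelines_logrank(ta, tb, ea, eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)

    def test_arm_without_events_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test([1.0, 2.0], [0, 0], [1.0, 2.0], [1, 1])
        assert (chi2, p) == (0.0, 1.0)

    def test_invariant_to_arm_labeling_and_monotone_time_transform(self):
        rng = np.random.default_rng(7)
        ta, tb = rng.exponential(10, 30), rng.exponential(14, 30)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        ea[0] = eb[0] = 1
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-12)
        c3, _ = logrank_test(np.log1p(ta), ea, np.log1p(tb), eb)
        assert c1 == pytest.approx(c3, abs=1e-12)


class TestMedianSplitScreen:
    def _screen(self, x, time, event, **kw):
        n = x.shape[1]
        samples = [f"s{i}" for i in range(n)]
        m = ExpressionMatrix(
            "mRNA",
            pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])], columns=samples),
        )
        cl = make_clinical(samples, times=time, events=event)
        return km_median_split_screen(m, cl, **kw)

    def test_constant_feature_skipped(self):
        rng = np.random.default_rng(0)
        x = np.vstack([np.full(40, 2.0), rng.normal(size=40)])
        res = self._screen(x, rng.exponential(10, 40), np.ones(40, int))
        assert list(res["feature_id"]) == ["g1"]

    def test_risky_feature_detected_with_direction(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=(1, n))
        time = rng.exponential(10 * np.exp(-1.5 * x[0]))
        res = self._screen(x, time, np.ones(n, int))
        assert bool(res.loc[0, "passes"])
        assert res.loc[0, "direction"] == "high_risk"

    def test_null_features_pass_at_about_alpha(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=(400, n))
        res = self._screen(x, rng.exponential(10, n), np.ones(n, int))
        assert 0.01 <= res["passes"].mean() <= 0.09

    def test_invariant_to_monotone_expression_transform(self):
        rng = np.random.default_rng(3)
        n = 100
        x = rng.normal(size=(5, n))
        time, event = rng.exponential(10, n), np.ones(n, int)
        a = self._screen(x, time, event)
        b = self._screen(np.exp(x), time, event)
        np.testing.assert_allclose(a["chi2"], b["chi2"], atol=1e-12)

    def test_true_survival_genes_detected(self, default_cohort):
        surv = km_median_split_screen(
            default_cohort.mrna, default_cohort.clinical,
            default_cohort.truth.true_survival_genes,
        )
        assert surv["passes"].all()


class TestPruneNetwork:
    def _pairs(self, mrnas):
        return [CeRNAPair("l1", m, ("m1",), 0.5, 0.01, 0.01, 0.9, True) for m in mrnas]

    def _surv(self, rows):
        return pd.DataFrame(
            [
                dict(feature_id=f, cut=0.0, chi2=1.0, p_logrank=p,
                     direction="high_risk", passes=p < 0.05)
                for f, p in rows
            ]
        )

    def test_half_pass_keeps_exactly_matching_pairs(self):
        pairs = self._pairs(["a", "b", "c", "d"])
        surv = self._surv([("a", 0.01), ("b", 0.5), ("c", 0.001), ("d", 0.9)])
        kept, report = prune_network(pairs, surv)
        assert {p.mrna_id for p in kept} == {"a", "c"}
        assert report["n_pairs_retained"] == 2

    def test_all_pass_is_identity(self):
        pairs = self._pairs(["a", "b"])
        kept, _ = prune_network(pairs, self._surv([("a", 0.01), ("b", 0.01)]))
        assert kept == pairs

    def test_none_pass_warns_and_empties(self):
        pairs = self._pairs(["a"])
        with pytest.warns(UserWarning, match="removed every pair"):
            kept, _ = prune_network(pairs, self._surv([("a", 0.9)]))
        assert kept == []


def test_cox_wrapper_recovers_risk_direction():
    rng = np.random.default_rng(4)
    n = 300
    risky = rng.normal(size=n)
    time = rng.exponential(10 * np.exp(-0.8 * risky))
    cl = make_clinical([f"s{i}" for i in range(n)], times=time, events=[1] * n)
    cl.data["risky"] = risky
    fit = cox_regression(cl, ["risky"])
    assert fit.summary.loc["risky", "coef"] > 0.5
    assert fit.summary.loc["risky", "p"] < 0.01
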