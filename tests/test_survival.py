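"""Survival-primitive oracles: exhaustive C-index pair enumeration,
log-rank calibration, Cox parameter recovery, hand KM computation, and the
weighted time-dependent AUC against an independent library estimator."""

import numpy as np
import pandas as pd
import pytest

from omisurv.containers import SurvivalData
from omisurv.survival import (
    concordance_index,
    km_curve,
    logrank_test,
    multivariate_cox,
    naive_binary_auc,
    time_dependent_auc,
    univariate_cox_screen,
)

from conftest import random_survival


def cindex_oracle(risk, time, event):
    """Exhaustive enumeration: a pair is comparable iff the smaller
    observed time is an event; concordant when higher risk has the shorter
    time; tied risks count 1/2."""
    n = len(risk)
    num, den = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j] or event[i] != 1:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_concordance_no_censoring(self, rng):
        surv = SurvivalData(
            rng.exponential(10, 20) + 0.1, np.ones(20), [f"S{i}" for i in range(20)]
        )
        assert concordance_index(-surv.time, surv) == 1.0

    def test_all_tied_scores_half(self, rng):
        surv = random_survival(rng, 15)
        assert concordance_index(np.zeros(15), surv) == 0.5

    def test_six_sample_toy_matches_oracle(self):
        time = np.array([2.0, 4.0, 4.0, 6.0, 7.0, 9.0])
        event = np.array([1, 0, 1, 1, 0, 0])
        risk = np.array([3.0, 1.0, 3.0, 2.0, 0.5, 1.5])
        surv = SurvivalData(time, event, [f"S{i}" for i in range(6)])
        assert concordance_index(risk, surv) == pytest.approx(
            cindex_oracle(risk, time, event)
        )

    def test_antisymmetry_without_ties(self, rng):
        surv = random_survival(rng, 30)
        risk = rng.standard_normal(30)
        c1 = concordance_index(risk, surv)
        c2 = concordance_index(-risk, surv)
        assert c1 + c2 == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self, rng):
        surv = random_survival(rng, 25)
        risk = rng.standard_normal(25)
        a = concordance_index(risk, surv)
        b = concordance_index(np.exp(3 * risk) + 7, surv)
        assert a == pytest.approx(b)

    def test_no_comparable_pairs_raises(self):
        surv = SurvivalData([1.0, 2.0], [0, 0], ["a", "b"])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), surv)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.tile([3.0, 5.0, 8.0, 11.0], 2)
        event = np.tile([1, 0, 1, 1], 2)
        labels = np.repeat([0, 1], 4)
        surv = SurvivalData(time, event, [f"S{i}" for i in range(8)])
        stat, p = logrank_test(labels, surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        surv = random_survival(rng, 40)
        labels = rng.integers(0, 2, 40)
        s1, _ = logrank_test(labels, surv)
        s2, _ = logrank_test(1 - labels, surv)
        assert s1 == pytest.approx(s2)

    def test_single_group_raises(self, rng):
        surv = random_survival(rng, 10)
        with pytest.raises(ValueError):
            logrank_test(np.zeros(10), surv)


class TestCox:
    def test_null_feature_selection_rate(self):
        """Pure-noise feature selected at ~alpha over replicates."""
        hits = 0
        reps = 500
        for seed in range(reps):
            rs = np.random.default_rng(seed)
            surv = random_survival(rs, 200)
            features = pd.DataFrame({"x": rs.standard_normal(200)})
            selected, _ = univariate_cox_screen(features, surv)
            hits += "x" in selected
        assert 0.03 <= hits / reps <= 0.07

    def test_strong_feature_always_selected(self):
        """Feature proportional to an HR=3 group indicator is selected."""
        hits = 0
        for seed in range(20):
            rs = np.random.default_rng(seed)
            z = rs.integers(0, 2, 300)
            time = rs.exponential(1.0 / np.where(z == 1, 3.0, 1.0)) + 1e-4
            event = np.ones(300, dtype=int)
            surv = SurvivalData(time, event, [f"S{i}" for i in range(300)])
            selected, _ = univariate_cox_screen(pd.DataFrame({"x": 2.0 * z}), surv)
            hits += "x" in selected
        assert hits == 20

    def test_constant_feature_skipped(self, rng):
        surv = random_survival(rng, 50)
        with pytest.warns(RuntimeWarning, match="constant"):
            selected, fits = univariate_cox_screen(
                pd.DataFrame({"c": np.ones(50)}), surv
            )
        assert selected == [] and "c" not in fits

    def test_single_covariate_multivariate_matches_screen(self, rng):
        surv = random_survival(rng, 100)
        x = pd.DataFrame({"f": rng.standard_normal(100)})
        _, fits = univariate_cox_screen(x, surv, alpha=1.1)
        joint = multivariate_cox(x, surv)
        assert joint.coefficient("f") == pytest.approx(
            fits["f"].coefficient("f"), rel=1e-6
        )

    def test_parameter_recovery_beta_1_minus1(self):
        """Cox-simulated data with beta=(1,-1): sign-correct within 3 SE."""
        good = 0
        reps = 100
        for seed in range(reps):
            rs = np.random.default_rng(seed)
            x = rs.standard_normal((1000, 2))
            lam = np.exp(x[:, 0] - x[:, 1])
            t_event = rs.exponential(1.0 / lam)
            t_cens = rs.exponential(np.quantile(t_event, 0.8), size=1000)
            time = np.maximum(np.minimum(t_event, t_cens), 1e-9)
            event = (t_event <= t_cens).astype(int)
            surv = SurvivalData(time, event, [f"S{i}" for i in range(1000)])
            fit = multivariate_cox(pd.DataFrame({"a": x[:, 0], "b": x[:, 1]}), surv)
            ok = (
                abs(fit.coefficient("a") - 1.0) < 3 * fit.standard_errors[0]
                and abs(fit.coefficient("b") + 1.0) < 3 * fit.standard_errors[1]
                and fit.coefficient("a") > 0 > fit.coefficient("b")
            )
            good += ok
        assert good >= 95

    def test_collinear_design_raises(self, rng):
        surv = random_survival(rng, 50)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            multivariate_cox(df, surv)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [0, 0, 0], ["a", "b", "c"])
        km = km_curve(surv)
        np.testing.assert_allclose(km["survival"], 1.0)

    def test_three_events_closed_form(self):
        surv = SurvivalData([1.0, 2.0, 3.0], [1, 1, 1], ["a", "b", "c"])
        km = km_curve(surv)
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_censoring_toy_matches_hand_product_limit(self):
        # events at 2 (4 at risk) and 5 (2 at risk); censored at 3 and 6
        surv = SurvivalData([2.0, 3.0, 5.0, 6.0], [1, 0, 1, 0], list("abcd"))
        km = km_curve(surv)
        lookup = dict(zip(km["time"], km["survival"]))
        assert lookup[2.0] == pytest.approx(3 / 4)
        assert lookup[5.0] == pytest.approx(3 / 4 * 1 / 2)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = np.sort(rng.exponential(5, 30)) + 0.01
        surv = SurvivalData(time, np.ones(30), [f"S{i}" for i in range(30)])
        km = km_curve(surv)
        for t, s in zip(km["time"][1:], km["survival"][1:]):
            assert s == pytest.approx((time > t).mean())


class TestTimeDependentAUC:
    def test_perfect_ranking_no_censoring(self, rng):
        time = rng.exponential(50, 200) + 0.1
        surv = SurvivalData(time, np.ones(200), [f"S{i}" for i in range(200)])
        auc, _ = time_dependent_auc(-time, surv, np.median(time))
        assert auc == pytest.approx(1.0)

    def test_null_risk_auc_half(self):
        vals = []
        for seed in range(5):
            rs = np.random.default_rng(seed)
            surv = random_survival(rs, 2000, censor_frac=0.3)
            risk = rs.standard_normal(2000)
            auc, _ = time_dependent_auc(risk, surv, float(np.median(surv.time)))
            vals.append(auc)
        assert abs(np.mean(vals) - 0.5) < 0.03

    def test_censoring_free_reduces_to_binary_auc(self, rng):
        time = rng.exponential(30, 150) + 0.1
        surv = SurvivalData(time, np.ones(150), [f"S{i}" for i in range(150)])
        risk = -time + rng.standard_normal(150) * 10
        horizon = float(np.median(time))
        auc, _ = time_dependent_auc(risk, surv, horizon)
        assert auc == pytest.approx(naive_binary_auc(risk, surv, horizon), abs=1e-10)

    def test_matches_library_ipcw_estimator(self, rng):
        """Independent cross-check against scikit-survival's
        cumulative/dynamic AUC with identical IPCW weighting."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        surv = random_survival(rng, 300, censor_frac=0.25)
        risk = -surv.time + rng.standard_normal(300) * 20
        horizon = float(np.quantile(surv.time, 0.5))
        auc, _ = time_dependent_auc(risk, surv, horizon)
        y = Surv.from_arrays(surv.event.astype(bool), surv.time)
        ref_auc, _ = cumulative_dynamic_auc(y, y, risk, [horizon])
        assert auc == pytest.approx(float(ref_auc[0]), abs=0.02)

    def test_roc_points_monotone(self, rng):
        surv = random_survival(rng, 100)
        risk = rng.standard_normal(100)
        _, roc = time_dependent_auc(risk, surv, float(np.median(surv.time)))
        assert (np.diff(roc["fpr"]) >= -1e-12).all()
        assert (np.diff(roc["tpr"]) >= -1e-12).all()

    def test_horizon_outside_range_raises(self, rng):
        surv = random_survival(rng, 50)
        with pytest.raises(ValueError, match="horizon"):
            time_dependent_auc(rng.standard_normal(50), surv, surv.time.max() + 1)
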