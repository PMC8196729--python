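"""Risk panel: score arithmetic oracle, cutpoint-search oracle and
invariances, null behaviour of the optimized log-rank split, and
coefficient sign recovery from a known linear risk model."""

import numpy as np
import pandas as pd
import pytest

from omisurv.containers import SurvivalData
from omisurv.risk_panel import (
    RiskPanel,
    compute_risk_scores,
    evaluate_panel,
    find_cutoff,
    fit_panel,
    pick_panel_features,
)
from omisurv.survival import concordance_index, logrank_test

from conftest import random_survival


def intersection_of(kind, fids, p_a, p_b):
    return pd.DataFrame(
        {
            "kind": kind,
            "feature_id": fids,
            "p_a": p_a,
            "p_b": p_b,
            "direction_a": "+",
            "direction_b": "+",
            "concordant": True,
        }
    )


class TestPickPanelFeatures:
    def test_two_smallest_mean_p_per_omics(self):
        report = {
            "expression": intersection_of(
                "expression", ["a", "b", "c"], [0.5, 0.01, 0.04], [0.3, 0.03, 0.02]
            ),
            "mirna": intersection_of("mirna", ["m1", "m2"], [0.2, 0.1], [0.2, 0.3]),
        }
        picked = pick_panel_features(report, per_omics_count=2)
        assert picked == ["b", "c", "m1", "m2"]

    def test_short_intersection_warns(self):
        report = {"expression": intersection_of("expression", ["a"], [0.1], [0.1])}
        with pytest.raises(Warning):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("error")
                pick_panel_features(report, per_omics_count=2)


class TestRiskScores:
    def _panel(self, beta):
        return RiskPanel(features=[f"f{i}" for i in range(len(beta))],
                         coefficients=np.asarray(beta), cutoff=0.0)

    def test_zero_beta_zero_scores(self, rng):
        x = pd.DataFrame(rng.standard_normal((10, 2)), columns=["f0", "f1"])
        np.testing.assert_array_equal(
            compute_risk_scores(self._panel([0.0, 0.0]), x), 0.0
        )

    def test_simple_arithmetic(self):
        x = pd.DataFrame({"f0": [2.0], "f1": [3.0]})
        assert compute_risk_scores(self._panel([1.0, -1.0]), x)[0] == -1.0

    def test_matches_double_loop_oracle(self, rng):
        beta = rng.standard_normal(6)
        x = pd.DataFrame(
            rng.standard_normal((20, 6)), columns=[f"f{i}" for i in range(6)]
        )
        scores = compute_risk_scores(self._panel(beta), x)
        for i in range(20):
            expected = sum(beta[j] * x.iloc[i, j] for j in range(6))
            assert scores[i] == pytest.approx(expected, abs=1e-12)

    def test_linearity(self, rng):
        beta = rng.standard_normal(3)
        cols = ["f0", "f1", "f2"]
        a = pd.DataFrame(rng.standard_normal((15, 3)), columns=cols)
        b = pd.DataFrame(rng.standard_normal((15, 3)), columns=cols)
        panel = self._panel(beta)
        np.testing.assert_allclose(
            compute_risk_scores(panel, a + b),
            compute_risk_scores(panel, a) + compute_risk_scores(panel, b),
            atol=1e-12,
        )

    def test_missing_feature_named(self, rng):
        x = pd.DataFrame({"f0": [1.0]})
        with pytest.raises(KeyError, match="f1"):
            compute_risk_scores(self._panel([1.0, 2.0]), x)


def cutoff_oracle(scores, surv):
    """Independent candidate-by-candidate scan."""
    uniq = np.sort(np.unique(scores))
    lo, hi = np.percentile(scores, [10, 90])
    best_stat, best_cut = -np.inf, None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        if not (lo <= c <= hi):
            continue
        groups = (scores > c).astype(int)
        if groups.min() == groups.max():
            continue
        stat, _ = logrank_test(groups, surv)
        if stat > best_stat:
            best_stat, best_cut = stat, c
    return best_cut


class TestFindCutoff:
    def test_gap_between_planted_clouds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            z = np.repeat([0, 1], n // 2)
            scores = np.where(z == 1, 10.0, 0.0) + rng.random(n)  # disjoint ranges
            time = rng.exponential(1.0 / np.where(z == 1, 5.0, 1.0)) + 1e-3
            surv = SurvivalData(time, np.ones(n), [f"S{i}" for i in range(n)])
            cut = find_cutoff(scores, surv)
            # the induced split recovers the planted clouds up to a couple
            # of boundary samples (the statistic is flat near the gap)
            agreement = ((scores > cut) == (z == 1)).mean()
            hits += agreement >= 0.97
        assert hits >= 9

    def test_internal_statistic_matches_lifelines(self, rng):
        from omisurv.risk_panel import _two_group_logrank_stat

        for _ in range(10):
            surv = random_survival(rng, 60)
            member = rng.random(60) < 0.4
            ref, _ = logrank_test(member.astype(int), surv)
            fast = _two_group_logrank_stat(member, surv.time, surv.event)
            assert fast == pytest.approx(ref, rel=1e-9)

    def test_matches_independent_scan(self, rng):
        surv = random_survival(rng, 50)
        scores = rng.standard_normal(50)
        assert find_cutoff(scores, surv) == pytest.approx(
            cutoff_oracle(scores, surv)
        )

    def test_partition_invariant_to_monotone_transform(self, rng):
        surv = random_survival(rng, 40)
        scores = rng.standard_normal(40)
        c1 = find_cutoff(scores, surv)
        c2 = find_cutoff(np.exp(scores), surv)
        np.testing.assert_array_equal(scores > c1, np.exp(scores) > c2)

    def test_constant_scores_raise(self, rng):
        surv = random_survival(rng, 20)
        with pytest.raises(ValueError, match="equal"):
            find_cutoff(np.ones(20), surv)


class TestEvaluatePanel:
    def _fitted(self, rng, n=400, signal=True):
        cols = [f"f{i}" for i in range(6)]
        x = pd.DataFrame(rng.standard_normal((n, 6)), columns=cols)
        beta_true = np.array([1.0, -1.0, 0.8, -0.6, 0.5, 0.0])
        lam = np.exp(x.to_numpy() @ beta_true) if signal else np.ones(n)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(np.quantile(t_event, 0.85), size=n)
        time = np.maximum(np.minimum(t_event, t_cens), 1e-9)
        event = (t_event <= t_cens).astype(int)
        surv = SurvivalData(time, event, [f"S{i}" for i in range(n)])
        return x, surv, beta_true

    def test_planted_signal_c_index(self):
        cs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, surv, _ = self._fitted(rng)
            panel = fit_panel(list(x.columns), x, surv)
            report = evaluate_panel(panel, x, surv)
            cs.append(report["c_index"])
        assert np.mean(cs) >= 0.65

    def test_null_scores_c_near_half_p_inflated(self):
        cs, ps = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 1000
            x = pd.DataFrame(
                rng.standard_normal((n, 3)), columns=["f0", "f1", "f2"]
            )
            surv = random_survival(rng, n)
            panel = RiskPanel(
                features=list(x.columns), coefficients=rng.standard_normal(3),
                cutoff=0.0,
            )
            scores = compute_risk_scores(panel, x)
            panel.cutoff = find_cutoff(scores, surv)
            report = evaluate_panel(panel, x, surv, horizon=float(np.median(surv.time)))
            cs.append(report["c_index"])
            ps.append(report["logrank_p"])
        assert abs(np.mean(cs) - 0.5) < 0.03
        # optimized cutpoint inflates small p-values above the nominal rate
        assert np.mean(np.array(ps) < 0.05) > 0.05

    def test_sign_recovery_of_strong_coefficients(self):
        """|beta| >= 0.5 recovered with correct signs in >= 95% of runs."""
        good = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x, surv, beta_true = self._fitted(rng, n=400)
            panel = fit_panel(list(x.columns), x, surv, screen_alpha=1.1)
            est = dict(zip(panel.features, panel.coefficients))
            ok = all(
                np.sign(est[f"f{i}"]) == np.sign(beta_true[i])
                for i in range(6)
                if abs(beta_true[i]) >= 0.5
            )
            good += ok
        assert good >= 95

    def test_group_above_cutoff_has_higher_mean_score(self, rng):
        x, surv, _ = self._fitted(rng, n=200)
        panel = fit_panel(list(x.columns), x, surv)
        scores = compute_risk_scores(panel, x)
        high = scores > panel.cutoff
        assert scores[high].mean() > scores[~high].mean()

    def test_report_schema_with_clinical(self, rng):
        x, surv, _ = self._fitted(rng, n=250)
        clinical = pd.DataFrame(
            {
                "age": rng.normal(60, 5, 250),
                "gleason": rng.integers(6, 11, 250),
                "stage": rng.choice(["I", "II", "III", "IV"], 250),
            },
            index=x.index,
        )
        panel = fit_panel(list(x.columns), x, surv)
        report = evaluate_panel(
            panel, x, surv, clinical=clinical, horizon=float(np.median(surv.time))
        )
        for key in ("c_index", "logrank_p", "auc", "km_high", "km_low", "clinical"):
            assert key in report
        assert report["clinical"]["c_index"] >= 0.0
        assert len(report["clinical"]["features"]) == len(panel.features) + 3
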