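"""KNN classification, Kaplan–Meier, log-rank and logistic model checks
against hand/closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tspsr.diffexp import AnalysisParams, Comparison, ComparisonResult
from tspsr.risk import (
    KnnModel,
    METASTASIS_LIKE,
    NORMAL_LIKE,
    fit_logistic,
    km_estimate,
    knn_classify,
    logrank,
    rank_features,
)


def _nvsm_result(rows):
    table = pd.DataFrame(rows).set_index("psr_id")
    return ComparisonResult(Comparison.NvsM, table, AnalysisParams())


class TestRankFeatures:
    def _rows(self, n_de, n_flat=20):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n_de):
            p = rng.uniform(1e-8, 1e-3)
            rows.append({"psr_id": f"de{i:03d}", "t": 5 + rng.uniform(), "p": p,
                         "q": p, "mfd": 1.6, "de": True, "direction": "UP"})
        for i in range(n_flat):
            rows.append({"psr_id": f"fl{i:03d}", "t": 0.2, "p": 0.6, "q": 0.7,
                         "mfd": 1.0, "de": False, "direction": "NONE"})
        return rows

    def test_top_n_by_p(self):
        rows = self._rows(250)
        feats = rank_features(_nvsm_result(rows), 100)
        assert len(feats) == 100
        ps = {r["psr_id"]: r["p"] for r in rows}
        cutoff = sorted(p for r, p in ps.items() if r.startswith("de"))[99]
        assert all(ps[f] <= cutoff for f in feats)

    def test_fewer_than_requested_warns(self):
        with pytest.warns(UserWarning, match="only 40"):
            feats = rank_features(_nvsm_result(self._rows(40)), 100)
        assert len(feats) == 40

    def test_input_order_irrelevant(self):
        rows = self._rows(60)
        a = rank_features(_nvsm_result(rows), 30)
        b = rank_features(_nvsm_result(rows[::-1]), 30)
        assert a == b

    def test_zero_de_features_error(self):
        with pytest.raises(ValueError, match="relax"):
            rank_features(_nvsm_result(self._rows(0)), 10)


class TestKnn:
    def _model(self):
        ref = pd.DataFrame(
            {"nA": [0.0, 0.0], "nB": [1.0, 0.0], "mA": [10.0, 10.0]},
            index=["f1", "f2"],
        )
        labels = pd.Series({"nA": "NORMAL", "nB": "NORMAL", "mA": "METASTASIS"})
        return KnnModel(ref, labels, ["f1", "f2"])

    def test_hand_distances(self):
        model = self._model()
        q = pd.DataFrame({"q1": [1.0, 1.0], "q2": [10.0, 10.0]}, index=["f1", "f2"])
        out = knn_classify(model, q)
        assert out["q1"] == NORMAL_LIKE       # d=1.41 to nA vs 12.7 to mA
        assert out["q2"] == METASTASIS_LIKE   # identical to a metastasis reference

    def test_tie_goes_to_lexicographically_first(self):
        ref = pd.DataFrame({"b_met": [2.0], "a_norm": [0.0]}, index=["f"])
        labels = pd.Series({"b_met": "METASTASIS", "a_norm": "NORMAL"})
        model = KnnModel(ref, labels, ["f"])
        q = pd.DataFrame({"q": [1.0]}, index=["f"])  # equidistant
        with pytest.warns(UserWarning, match="tie"):
            out = knn_classify(model, q)
        assert out["q"] == NORMAL_LIKE  # a_norm sorts before b_met

    def test_missing_feature_error(self):
        model = self._model()
        with pytest.raises(ValueError, match="f2"):
            knn_classify(model, pd.DataFrame({"q": [1.0]}, index=["f1"]))

    def test_invariances(self):
        """Feature order and a global constant shift leave predictions alone."""
        rng = np.random.default_rng(8)
        feats = [f"f{i}" for i in range(12)]
        ref = pd.DataFrame(rng.normal(7, 1, (12, 10)), index=feats,
                           columns=[f"r{i}" for i in range(10)])
        labels = pd.Series(["NORMAL"] * 5 + ["METASTASIS"] * 5, index=ref.columns)
        q = pd.DataFrame(rng.normal(7, 1, (12, 6)), index=feats,
                         columns=[f"q{i}" for i in range(6)])
        base = knn_classify(KnnModel(ref, labels, feats), q)
        shuffled = list(feats[::-1])
        again = knn_classify(KnnModel(ref.loc[shuffled], labels, shuffled), q.loc[shuffled])
        pd.testing.assert_series_equal(base, again)
        shifted = knn_classify(KnnModel(ref + 3.5, labels, feats), q + 3.5)
        pd.testing.assert_series_equal(base, shifted)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        out = km_estimate([1, 2, 3], [True, True, True], ["g"] * 3)["g"]
        np.testing.assert_allclose(out["survival"], [2 / 3, 1 / 3, 0.0])
        assert out["at_risk"].tolist() == [3, 2, 1]

    def test_no_events_flat_curve(self):
        out = km_estimate([5, 6, 7], [False] * 3, ["g"] * 3)["g"]
        np.testing.assert_allclose(out["survival"], 1.0)

    def test_early_censoring_reduces_at_risk_not_survival(self):
        base = km_estimate([2, 3], [True, True], ["g"] * 2)["g"]
        cens = km_estimate([1, 2, 3], [False, True, True], ["g"] * 3)["g"]
        ev = cens[cens["events"] > 0]
        np.testing.assert_allclose(ev["survival"].to_numpy(), base["survival"].to_numpy())
        assert ev["at_risk"].tolist() == base["at_risk"].tolist()

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(10, size=40)
        out = km_estimate(t, [True] * 40, ["g"] * 40)["g"]
        emp = [(t > ti).mean() for ti in out["time"]]
        np.testing.assert_allclose(out["survival"], emp, atol=1e-12)


def hand_logrank(times, events, labels):
    """O-E tally over distinct event times (oracle implementation)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    labels = np.asarray(labels)
    g0 = sorted(set(labels))[0]
    obs0 = exp0 = var = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (labels == g0)).sum()
        d = (events & (times == t)).sum()
        d0 = (events & (times == t) & (labels == g0)).sum()
        obs0 += d0
        exp0 += d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    chi = (obs0 - exp0) ** 2 / var
    return chi, stats.chi2.sf(chi, df=1)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4] * 2
        e = [True] * 8
        g = ["a"] * 4 + ["b"] * 4
        out = logrank(t, e, g)
        assert out["chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_hand_oe_computation(self):
        rng = np.random.default_rng(21)
        t = np.concatenate([rng.exponential(5, 30), rng.exponential(12, 30)])
        e = rng.uniform(size=60) < 0.8
        g = np.array(["a"] * 30 + ["b"] * 30)
        out = logrank(t, e, g)
        chi, p = hand_logrank(t, e, g)
        assert out["chi_square"] == pytest.approx(chi, rel=1e-9)
        assert out["p"] == pytest.approx(p, rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(22)
        t = rng.exponential(5, 40)
        e = rng.uniform(size=40) < 0.7
        g = np.where(rng.uniform(size=40) < 0.5, "a", "b")
        flipped = np.where(g == "a", "b", "a")
        assert logrank(t, e, g)["chi_square"] == pytest.approx(
            logrank(t, e, flipped)["chi_square"], rel=1e-12
        )

    def test_permutation_null_matches_chi_square_p(self):
        """The chi-square p agrees with a 2000-permutation label null."""
        rng = np.random.default_rng(23)
        t = np.concatenate([rng.exponential(5, 25), rng.exponential(9, 25)])
        e = rng.uniform(size=50) < 0.8
        g = np.array(["a"] * 25 + ["b"] * 25)
        ref = logrank(t, e, g)
        stat_ref = ref["chi_square"]
        exceed = 0
        n_perm = 2000
        # the hand statistic equals the production one (asserted above),
        # so the permutation null can use the cheap implementation
        for _ in range(n_perm):
            gp = rng.permutation(g)
            if hand_logrank(t, e, gp)[0] >= stat_ref:
                exceed += 1
        p_perm = (exceed + 1) / (n_perm + 1)
        mc_sd = np.sqrt(ref["p"] * (1 - ref["p"]) / n_perm)
        assert abs(p_perm - ref["p"]) < 4 * mc_sd + 1e-3

    def test_group_errors(self):
        with pytest.raises(ValueError):
            logrank([1, 2], [True, True], ["a", "a"])


class TestLogistic:
    def test_2x2_cross_product_ratio_exact(self):
        """Single binary covariate: OR equals (8*8)/(2*2) = 16."""
        y = [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8
        x = pd.DataFrame({"exposed": [1] * 10 + [0] * 10})
        (s,) = fit_logistic(y, x)
        assert s.odds_ratio == pytest.approx(16.0, rel=1e-6)
        assert s.ci95[0] < 16.0 < s.ci95[1]
        assert not s.separation

    def test_independent_covariate_or_near_one(self):
        y = [True, False] * 20
        x = pd.DataFrame({"z": ([1, 1, 0, 0] * 10)})
        (s,) = fit_logistic(y, x)
        assert s.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_flagged(self):
        y = [True] * 10 + [False] * 10
        x = pd.DataFrame({"z": [1] * 10 + [0] * 10})
        (s,) = fit_logistic(y, x)
        assert s.separation

    def test_wald_ci_hand_check(self):
        """CI bounds equal exp(beta ± 1.96*se) from the fitted model."""
        rng = np.random.default_rng(31)
        x = rng.integers(0, 2, size=200)
        z = rng.integers(0, 2, size=200)
        logit = -0.5 + 0.9 * x + 0.4 * z
        y = rng.uniform(size=200) < 1 / (1 + np.exp(-logit))
        out = fit_logistic(y, pd.DataFrame({"x": x, "z": z}))
        import statsmodels.api as sm

        X = sm.add_constant(pd.DataFrame({"x": x, "z": z}).astype(float))
        fit = sm.Logit(y.astype(float), X).fit(disp=0)
        for s in out:
            beta = fit.params[s.covariate]
            se = np.sqrt(fit.cov_params().loc[s.covariate, s.covariate])
            assert s.odds_ratio == pytest.approx(np.exp(beta), rel=1e-6)
            assert s.ci95[0] == pytest.approx(np.exp(beta - 1.959963984540054 * se), rel=1e-6)
            assert s.ci95[1] == pytest.approx(np.exp(beta + 1.959963984540054 * se), rel=1e-6)
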