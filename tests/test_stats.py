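"""Statistical battery: t-tests, categorical tests, mixed ANOVA, ROC,
DeLong, clustering, CHA2DS2-VASc."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lastrain.stats import (StatReport, categorical_test, chads_vasc,
                            cluster_phenotypes, delong_test, mixed_anova,
                            roc_analysis, t_test, t_test_summary)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    """Brute-force concordant-pair AUC with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def fisher_enumeration(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = sps.hypergeom.pmf(k, n, c1, r1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestTTests:
    def test_identical_groups_give_p_one(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r = t_test([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.p == pytest.approx(0.0214, abs=1e-3)
        assert r.df == 4

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 1.3, 23)
        r = t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_summary_agrees_with_samples_on_moment_matched_data(self):
        """Samples constructed to have exactly the printed moments give
        the same result through both routes to 1e-12."""
        rng = np.random.default_rng(1)
        for mean, sd, n in [(9.3, 6.0, 18), (15.9, 9.1, 51)]:
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            x = mean + sd * z
            other = rng.normal(5, 2, 20)
            r1 = t_test(x, other)
            r2 = t_test_summary(x.mean(), x.std(ddof=1), n,
                                other.mean(), other.std(ddof=1), 20)
            assert r1.p == pytest.approx(r2.p, abs=1e-12)
            assert r1.t == pytest.approx(r2.t, abs=1e-12)

    def test_zero_variance_cases(self):
        same = t_test_summary(5.0, 0.0, 5, 5.0, 0.0, 5)
        assert same.p == 1.0
        diff = t_test_summary(5.0, 0.0, 5, 6.0, 0.0, 5)
        assert np.isnan(diff.p) and "unequal means" in diff.flag

    def test_welch_flag_changes_df(self):
        r = t_test_summary(12.7, 8.9, 21, 8.7, 5.2, 48, welch=True)
        assert r.test == "welch_t"
        assert r.df != 67


class TestCategorical:
    def test_symmetric_table_gives_p_one(self):
        assert categorical_test([[1, 1], [1, 1]]).p == pytest.approx(1.0)

    def test_perfect_separation(self):
        r = categorical_test([[10, 0], [0, 10]], method="fisher")
        from math import comb
        assert r.p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_auto_rule_uses_fisher_for_small_expected_counts(self):
        r = categorical_test([[2, 3], [1, 4]])
        assert r.test == "fisher_exact"
        r2 = categorical_test([[20, 30], [25, 28]])
        assert r2.test == "chi2_yates"

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty margin"):
            categorical_test([[0, 0], [3, 4]])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15), st.integers(0, 15))
    def test_fisher_matches_enumeration_margins_le_30(self, a, b, c, d):
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p = categorical_test([[a, b], [c, d]], method="fisher").p
        assert p == pytest.approx(fisher_enumeration([[a, b], [c, d]]),
                                  abs=1e-9)


class TestMixedAnova:
    @staticmethod
    def _long(rng, n_per_group, effect=0.0, region_effect=None):
        rows = []
        for g in (0, 1):
            for s in range(n_per_group):
                sid = f"g{g}s{s}"
                base = rng.normal(0, 1)
                for i, r in enumerate("abcde"):
                    mu = g * effect
                    if region_effect is not None and g == 1:
                        mu += region_effect[i]
                    rows.append((sid, g, r, base + mu + rng.normal(0, 1)))
        return pd.DataFrame(rows, columns=["subj", "grp", "region", "y"])

    def test_uniform_group_effect_hits_group_not_interaction(self):
        rng = np.random.default_rng(4)
        df = self._long(rng, 30, effect=1.5)
        r = mixed_anova(df, "y", "subj", "grp", "region")
        assert r.p_group < 0.01
        assert r.p_interaction > 0.05

    def test_region_specific_effect_hits_interaction(self):
        rng = np.random.default_rng(5)
        df = self._long(rng, 30, region_effect=[2.5, 0, 0, 0, -2.5])
        r = mixed_anova(df, "y", "subj", "grp", "region")
        assert r.p_interaction < 0.01
        assert r.p_interaction_gg < 0.05

    def test_missing_region_rejected(self):
        rng = np.random.default_rng(6)
        df = self._long(rng, 4).iloc[:-2]
        with pytest.raises(ValueError, match="missing within-factor"):
            mixed_anova(df, "y", "subj", "grp", "region")

    def test_single_subject_per_group_rejected(self):
        rng = np.random.default_rng(7)
        df = self._long(rng, 1)
        with pytest.raises(ValueError, match="at least 2 subjects"):
            mixed_anova(df, "y", "subj", "grp", "region")

    def test_interaction_type_i_error_near_nominal(self):
        """Null simulation (1000 reps): the interaction test rejects at
        ~5% with alpha = 0.05."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            df = self._long(rng, 6)
            r = mixed_anova(df, "y", "subj", "grp", "region")
            rejections += r.p_interaction < 0.05
        rate = rejections / n_reps
        assert 0.028 <= rate <= 0.072   # 5% +- 3 binomial sigma


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1],
                         n_boot=200, seed=0)
        assert r.auc == 1.0
        assert r.ci_high == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_four_point_pair_counting_example(self):
        r = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1], n_boot=200, seed=0)
        assert r.auc == 1.0
        # swap one pair: scores {1,2,3,4} with labels {0,1,0,1} has one
        # discordant pair (2 vs 3) -> AUC = 0.75 by pair counting
        r2 = roc_analysis([1, 2, 3, 4], [0, 1, 0, 1], n_boot=200, seed=0)
        assert r2.auc == 0.75

    def test_orientation_flip_recorded(self):
        # lower scores predict the event
        r = roc_analysis([10, 9, 8, 1, 2, 3], [0, 0, 0, 1, 1, 1],
                         n_boot=200, seed=0)
        assert r.auc == 1.0 and r.orientation == -1

    def test_independent_scores_drift_to_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        r = roc_analysis(scores, labels, n_boot=200, seed=0)
        assert r.auc == pytest.approx(0.5, abs=0.03)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=12),
           st.data())
    def test_auc_equals_pair_counting_n_le_12(self, scores, data):
        n = len(scores)
        labels = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n,
                                    max_size=n))
        if len(set(labels)) < 2:
            return
        r = roc_analysis(scores, labels, n_boot=200, seed=0)
        brute = auc_pair_counting(scores, labels)
        brute = max(brute, 1 - brute)   # implementation auto-orients
        assert r.auc == pytest.approx(brute, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(0, 1, 60)) > 0
        a1 = roc_analysis(scores, labels, n_boot=200, seed=0).auc
        a2 = roc_analysis(np.exp(3 * scores), labels, n_boot=200, seed=0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1], n_boot=200, seed=0)

    def test_bootstrap_ci_coverage_near_95(self):
        """Percentile-bootstrap CI covers the true binormal AUC ~95% of
        the time (within Monte-Carlo and small-sample bias tolerance)."""
        mu = 1.0
        true_auc = sps.norm.cdf(mu / np.sqrt(2))
        rng = np.random.default_rng(12)
        n_reps, covered = 400, 0
        for rep in range(n_reps):
            neg = rng.normal(0, 1, 50)
            pos = rng.normal(mu, 1, 50)
            scores = np.r_[neg, pos]
            labels = np.r_[np.zeros(50), np.ones(50)]
            r = roc_analysis(scores, labels, n_boot=400, seed=rep)
            covered += r.ci_low <= true_auc <= r.ci_high
        assert covered / n_reps == pytest.approx(0.95, abs=0.035)


class TestDeLong:
    @staticmethod
    def _correlated_scores(rng, n, auc1, auc2, rho=0.6):
        half = n // 2
        labels = np.r_[np.zeros(half), np.ones(n - half)]
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        mu1 = np.sqrt(2) * sps.norm.ppf(auc1)
        mu2 = np.sqrt(2) * sps.norm.ppf(auc2)
        s1 = z[:, 0] + mu1 * labels
        s2 = z[:, 1] + mu2 * labels
        return s1, s2, labels

    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        r = delong_test(s, s, y)
        assert r.delta == 0.0 and r.p == 1.0

    def test_monotone_transform_gives_zero_delta(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = (s + rng.normal(0, 1, 40)) > 0.2
        r = delong_test(s, np.tanh(2 * s) + 5, y.astype(int))
        assert r.delta == pytest.approx(0.0, abs=1e-12)
        assert r.p == 1.0

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_test([1, 2, 3], [1, 2], [0, 1, 1])

    def test_variance_estimate_and_power_match_simulation(self):
        """DeLong's variance tracks the empirical variance of the paired
        AUC difference, and the test's empirical power matches the
        normal-approximation power implied by the simulated delta
        distribution (independent simulation oracle, AUCs 0.80 vs 0.70,
        n = 200)."""
        rng = np.random.default_rng(2)
        n_reps = 400
        deltas, vars_, rejects = [], [], 0
        for _ in range(n_reps):
            s1, s2, y = self._correlated_scores(rng, 200, 0.80, 0.70)
            r = delong_test(s1, s2, y, orient="none")
            deltas.append(r.delta)
            vars_.append(r.variance)
            rejects += r.p < 0.05
        emp_var = np.var(deltas, ddof=1)
        assert np.mean(vars_) == pytest.approx(emp_var, rel=0.25)
        power = rejects / n_reps
        # normal-approx oracle power from the empirical delta distribution
        zcrit = sps.norm.ppf(0.975)
        pred = 1 - sps.norm.cdf(zcrit - np.mean(deltas) / np.sqrt(emp_var)) \
            + sps.norm.cdf(-zcrit - np.mean(deltas) / np.sqrt(emp_var))
        assert power == pytest.approx(pred, abs=0.10)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(3)
        rejects = 0
        n_reps = 300
        for _ in range(n_reps):
            s1, s2, y = self._correlated_scores(rng, 120, 0.75, 0.75)
            rejects += delong_test(s1, s2, y, orient="none").p < 0.05
        assert 0.02 <= rejects / n_reps <= 0.09


class TestClustering:
    @staticmethod
    def _blobs(rng, n=40, sep=6.0):
        a = rng.normal(0, 1, size=(n, 36))
        b = rng.normal(sep, 1, size=(n, 36))
        x = pd.DataFrame(np.vstack([a, b]),
                         index=[f"s{i}" for i in range(2 * n)])
        truth = np.r_[np.zeros(n), np.ones(n)]
        return x, truth

    def test_two_blobs_selects_k2_with_perfect_assignment(self):
        rng = np.random.default_rng(0)
        x, truth = self._blobs(rng)
        r = cluster_phenotypes(x, k_range=range(2, 6), seed=0)
        assert r.chosen_k == 2
        lab = r.assignments.values
        agreement = max((lab == truth).mean(), (lab != truth).mean())
        assert agreement == 1.0
        assert r.explained_variance_ratio[0] > 0.5

    def test_sole_member_outlier_removed_and_reclustered(self):
        rng = np.random.default_rng(1)
        x, _ = self._blobs(rng, n=20, sep=5.0)
        x.loc["outlier"] = 60.0
        r = cluster_phenotypes(x, k_range=range(2, 5), seed=0)
        assert "outlier" in r.removed_outliers
        assert "outlier" not in r.assignments.index
        assert r.chosen_k == 2

    def test_identical_rows_rejected(self):
        x = pd.DataFrame(np.ones((10, 36)))
        with pytest.raises(ValueError, match="degenerate"):
            cluster_phenotypes(x, seed=0)

    def test_k_range_exceeding_n_rejected(self):
        rng = np.random.default_rng(2)
        x, _ = self._blobs(rng, n=3)
        with pytest.raises(ValueError, match="k_range"):
            cluster_phenotypes(x, k_range=range(2, 10), seed=0)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        x, _ = self._blobs(rng, n=15, sep=2.0)
        r1 = cluster_phenotypes(x, seed=7)
        r2 = cluster_phenotypes(x, seed=7)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        assert r1.silhouette_by_k == r2.silhouette_by_k


class TestChadsVasc:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(chf=False, hypertension=True, diabetes=False, stroke_tia=False,
              vascular_disease=False, age_y=62, female=True), 2),
        (dict(chf=False, hypertension=False, diabetes=False, stroke_tia=False,
              vascular_disease=False, age_y=80, female=False), 2),
        (dict(chf=True, hypertension=True, diabetes=True, stroke_tia=True,
              vascular_disease=True, age_y=80, female=True), 9),
        (dict(chf=False, hypertension=False, diabetes=False, stroke_tia=False,
              vascular_disease=False, age_y=70, female=False), 1),
    ])
    def test_rubric(self, kwargs, expected):
        assert chads_vasc(**kwargs) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            chads_vasc(chf=False, hypertension=False, diabetes=False,
                       stroke_tia=False, vascular_disease=False,
                       age_y=-1, female=False)


class TestStatReport:
    def test_round_trip_to_json(self, tmp_path):
        rep = StatReport()
        rep.add("t", t_test([1, 2, 3], [4, 5, 6]))
        rep.add("fisher", categorical_test([[13, 5], [35, 16]]))
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert loaded["fisher"]["p"] == pytest.approx(1.0)
        assert 0 <= loaded["t"]["p"] <= 1
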