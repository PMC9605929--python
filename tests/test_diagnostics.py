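"""ROC, DeLong, Youden, exact-CI summaries and classification rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gliodx import (
    ClassificationRule,
    ContingencyTable,
    classify_lesions,
    clopper_pearson,
    concordance_matrix,
    delong_test,
    logistic_combine,
    patientwise_analysis,
    roc_auc,
    summarize_contingency,
    youden_cutoff,
)
from gliodx.diagnostics import exact_odds_ratio_ci


def brute_force_auc(scores, labels):
    """Exhaustive pair-enumeration oracle (ties count one half)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (pos.size * neg.size)


def brute_force_youden(scores, labels):
    """Exhaustive threshold-scan oracle under the 'value > cut' convention."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = (-np.inf, None)
    for c in np.unique(s):
        j = (s[y] > c).mean() + (s[~y] <= c).mean() - 1.0
        if j > best[0] + 1e-12:
            best = (j, c)
    return best[1], best[0]


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0

    def test_toy_set_matches_pair_enumeration(self):
        scores = [3.0, 4.0, 1.0, 2.0, 3.0]
        labels = [1, 1, 0, 0, 0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels)
        )
        assert brute_force_auc(scores, labels) == pytest.approx(5.5 / 6.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n = rng.integers(4, 30)
            s = np.round(rng.normal(size=n), 1)  # rounded -> plenty of ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert roc_auc(s, y).auc == pytest.approx(brute_force_auc(s, y))

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
    def test_negation_symmetry(self, vals):
        s = np.asarray(vals)
        y = np.zeros(s.size, bool)
        y[: s.size // 2] = True
        if y.all() or not y.any():
            return
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestLogisticCombine:
    def test_single_covariate_matches_rank_auc(self, rng):
        x = rng.normal(size=60)
        y = rng.random(60) < 1 / (1 + np.exp(-x))
        lp = logistic_combine(pd.DataFrame({"x": x}), y)
        assert roc_auc(lp, y).auc == pytest.approx(roc_auc(x, y).auc)

    def test_constant_covariate_leaves_auc_unchanged(self, rng):
        x = rng.normal(size=60)
        y = rng.random(60) < 1 / (1 + np.exp(-x))
        lp1 = logistic_combine(pd.DataFrame({"x": x}), y)
        lp2 = logistic_combine(pd.DataFrame({"x": x, "c": np.ones(60)}), y)
        assert roc_auc(lp2, y).auc == pytest.approx(roc_auc(lp1, y).auc, abs=1e-9)

    def test_two_covariates_near_monotone_in_sample(self, rng):
        n = 150
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-(x1 + 0.5 * x2)))
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        lp = logistic_combine(pd.DataFrame({"a": x1, "b": x2}), y)
        auc2 = roc_auc(lp, y).auc
        assert auc2 >= roc_auc(x1, y).auc - 0.02
        assert auc2 >= roc_auc(x2, y).auc - 0.02

    def test_perfect_separation_falls_back_with_warning(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        with pytest.warns(UserWarning, match="rank AUC"):
            lp = logistic_combine(pd.DataFrame({"x": x}), y)
        assert roc_auc(lp, y).auc == 1.0


class TestDelong:
    def test_identical_classifiers(self, rng):
        s = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        d, p = delong_test(s, s, y)
        assert d == 0.0 and p == 1.0

    def test_monotone_transform_gives_zero_delta(self, rng):
        s = rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        d, _ = delong_test(s, np.exp(s), y)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_detects_clear_difference(self, rng):
        n = 200
        y = np.arange(n) % 2 == 0
        good = y.astype(float) + rng.normal(0, 0.3, n)
        junk = rng.normal(size=n)
        d, p = delong_test(good, junk, y)
        assert d > 0.3 and p < 1e-6


class TestYouden:
    def test_separable_example_tie_rule(self):
        cut, j = youden_cutoff([2.5, 3.0, 4.0, 1.0, 2.0], [1, 1, 1, 0, 0])
        assert cut == 2.0 and j == pytest.approx(1.0)

    def test_matches_exhaustive_scan_on_random_instances(self, rng):
        for _ in range(300):
            n = rng.integers(4, 25)
            s = np.round(rng.normal(size=n), 1)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            cut, j = youden_cutoff(s, y)
            cut_o, j_o = brute_force_youden(s, y)
            assert j == pytest.approx(j_o)
            assert cut == pytest.approx(cut_o)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        _, j1 = youden_cutoff(s, y)
        _, j2 = youden_cutoff(np.exp(s), y)
        assert j1 == pytest.approx(j2)

    def test_threshold_sweep_monotonicity(self, rng):
        # raising the cut-off never increases sensitivity nor decreases
        # specificity
        s = rng.normal(size=50)
        y = rng.random(50) < 0.4
        y[:2] = [True, False]
        sens = [np.mean(s[y] > c) for c in np.sort(np.unique(s))]
        spec = [np.mean(s[~y] <= c) for c in np.sort(np.unique(s))]
        assert np.all(np.diff(sens) <= 0)
        assert np.all(np.diff(spec) >= 0)


class TestClassificationRules:
    COHORT = pd.DataFrame(
        {
            "lesion_id": ["a", "b", "c", "d"],
            "enhancing": [True, True, False, True],
            "tbr_max": [2.4, 2.0, 1.6, 3.0],
            "bv_max": [12.0, 8.0, 1.0, 9.0],
            "outcome": ["progressive", "non-progressive", "progressive", "progressive"],
        }
    )

    def test_ce_cutoff_positive_call(self):
        rule = ClassificationRule("tbr_max", 2.27, 1.52)
        calls = classify_lesions(self.COHORT, rule).calls
        assert bool(calls.iloc[0]) is True    # 2.4 > 2.27, enhancing
        assert bool(calls.iloc[1]) is False   # 2.0 <= 2.27

    def test_non_enhancing_lesion_uses_non_ce_cutoff(self):
        rule = ClassificationRule("tbr_max", 2.27, 1.52)
        calls = classify_lesions(self.COHORT, rule).calls
        assert bool(calls.iloc[2]) is True    # 1.6 > 1.52 via non-CE cut-off

    def test_equality_is_negative(self):
        rule = ClassificationRule("tbr_max", 2.4)
        assert bool(classify_lesions(self.COHORT, rule).calls.iloc[0]) is False

    def test_concordant_and_requires_both(self):
        fet = ClassificationRule("tbr_max", 2.27, 1.52, mode="concordant-AND")
        bv = ClassificationRule("bv_max", 10.43, 2.28)
        calls = classify_lesions(self.COHORT, fet, secondary=bv).calls
        # lesion a: FET+ BV+ -> +; lesion d: FET+ BV- -> -
        assert bool(calls.iloc[0]) is True
        assert bool(calls.iloc[3]) is False

    def test_sequential_equals_boolean_or_truth_table(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "enhancing": np.ones(n, bool),
                "tbr_max": rng.uniform(1, 4, n),
                "bv_max": rng.uniform(0, 20, n),
            }
        )
        bv = ClassificationRule("bv_max", 10.43, mode="sequential-BV-first")
        fet = ClassificationRule("tbr_max", 2.27)
        res = classify_lesions(df, bv, secondary=fet)
        bv_pos = df["bv_max"] > 10.43
        fet_pos = df["tbr_max"] > 2.27
        expected = bv_pos | (~bv_pos & fet_pos)
        assert (res.calls.astype(bool) == expected).all()
        assert res.second_test_avoided == pytest.approx(bv_pos.mean())

    def test_concordant_specificity_sensitivity_set_inclusion(self, rng):
        df = pd.DataFrame(
            {
                "enhancing": np.ones(100, bool),
                "tbr_max": rng.uniform(1, 4, 100),
                "bv_max": rng.uniform(0, 20, 100),
                "outcome": np.where(rng.random(100) < 0.5, "progressive", "non-progressive"),
            }
        )
        y = df["outcome"].eq("progressive").to_numpy()
        fet = ClassificationRule("tbr_max", 2.27, mode="concordant-AND")
        bv = ClassificationRule("bv_max", 10.43)
        both = summarize_contingency(
            ContingencyTable.from_calls(classify_lesions(df, fet, secondary=bv).calls, y)
        )
        single = summarize_contingency(
            ContingencyTable.from_calls(classify_lesions(df, ClassificationRule("tbr_max", 2.27)).calls, y)
        )
        assert both.specificity >= single.specificity
        assert both.sensitivity <= single.sensitivity


class TestContingencySummary:
    def test_fet_lesionwise_counts(self):
        # TP 40 / FN 4 / FP 5 / TN 27
        s = summarize_contingency(ContingencyTable(tp=40, fp=5, fn=4, tn=27))
        assert s.sensitivity == pytest.approx(90.9, abs=0.05)
        assert s.specificity == pytest.approx(84.4, abs=0.05)
        assert s.odds_ratio == pytest.approx(54.0)
        assert s.accuracy == pytest.approx(88.2, abs=0.05)

    def test_all_predicted_positive(self):
        s = summarize_contingency(ContingencyTable(tp=10, fp=5, fn=0, tn=0))
        assert s.sensitivity == 100.0 and s.specificity == 0.0

    def test_division_by_zero_renders_na_not_exception(self):
        s = summarize_contingency(ContingencyTable(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(s.ppv)
        assert s.format_cell("ppv").startswith("n.a.")

    def test_clopper_pearson_matches_tail_enumeration(self):
        # independent oracle: invert the binomial tail probabilities on a grid
        k, n, alpha = 3, 28, 0.05
        lo, hi = clopper_pearson(k, n, alpha)
        grid = np.linspace(1e-6, 1 - 1e-6, 200001)
        upper_tail = stats.binom.sf(k - 1, n, grid)   # P(X >= k)
        lower_tail = stats.binom.cdf(k, n, grid)      # P(X <= k)
        lo_oracle = grid[np.searchsorted(upper_tail, alpha / 2)]
        hi_oracle = grid[len(grid) - 1 - np.searchsorted(lower_tail[::-1], alpha / 2)]
        assert lo == pytest.approx(lo_oracle, abs=2e-4)
        assert hi == pytest.approx(hi_oracle, abs=2e-4)

    def test_sensitivity_ci_matches_published_interval(self):
        # 40/44 -> 90.9 (78.3 - 97.5) with the exact method
        s = summarize_contingency(ContingencyTable(tp=40, fp=5, fn=4, tn=27))
        assert s.sensitivity_ci[0] == pytest.approx(78.3, abs=0.05)
        assert s.sensitivity_ci[1] == pytest.approx(97.5, abs=0.05)

    def test_exact_or_ci_unbounded_rendered_na(self):
        # patient-wise PET table: TP 38 / FP 0 / FN 5 / TN 16
        s = summarize_contingency(ContingencyTable(tp=38, fp=0, fn=5, tn=16))
        assert np.isinf(s.odds_ratio) or np.isnan(s.odds_ratio)
        assert s.format_value(s.odds_ratio) == "n.a."
        lo, hi = s.odds_ratio_ci
        assert np.isfinite(lo) and lo > 1.0
        assert np.isinf(hi)

    def test_or_ci_contains_point_estimate(self):
        lo, hi = exact_odds_ratio_ci(40, 5, 4, 27)
        assert lo < 54.0 < hi


class TestConcordanceMatrix:
    @staticmethod
    def fixture_cohort():
        """Cohort whose calls reproduce the published concordance cells:
        FET-BV- 3/28, FET-BV+ 1/3, FET+BV- 7/11, FET+BV+ 33/34."""
        rows = []
        cells = {
            (False, False): (3, 28),
            (False, True): (1, 3),
            (True, False): (7, 11),
            (True, True): (33, 34),
        }
        i = 0
        for (fet_pos, bv_pos), (k, n) in cells.items():
            for j in range(n):
                rows.append(
                    {
                        "lesion_id": f"L{i}",
                        "patient_id": f"P{i}",
                        "enhancing": True,
                        "tbr_max": 3.0 if fet_pos else 2.0,
                        "bv_max": 12.0 if bv_pos else 8.0,
                        "outcome": "progressive" if j < k else "non-progressive",
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    RULE_FET = ClassificationRule("tbr_max", 2.27)
    RULE_BV = ClassificationRule("bv_max", 10.43)

    def test_reproduces_published_cells(self):
        conc = concordance_matrix(self.fixture_cohort(), self.RULE_FET, self.RULE_BV)
        cells = {(r.fet, r.bv): (r.n_progressive, r.n_total) for r in conc.itertuples()}
        assert cells[("FET-", "BV-")] == (3, 28)
        assert cells[("FET-", "BV+")] == (1, 3)
        assert cells[("FET+", "BV-")] == (7, 11)
        assert cells[("FET+", "BV+")] == (33, 34)

    def test_identical_rules_empty_off_diagonal(self):
        df = self.fixture_cohort()
        conc = concordance_matrix(df, self.RULE_BV, self.RULE_BV)
        off = conc[(conc.fet == "FET-") & (conc.bv == "BV+")]["n_total"].iloc[0]
        assert off == 0

    def test_cells_partition_cohort_across_seeds(self):
        from gliodx import CohortSpec, simulate_cohort

        for seed in range(20):
            df = simulate_cohort(CohortSpec(seed=seed))
            conc = concordance_matrix(df, self.RULE_FET, self.RULE_BV)
            assert conc["n_total"].sum() == len(df)


class TestSubgroupFilters:
    def test_subgroup_analysis_is_a_row_filter(self):
        # stratified reruns (enhancing-only, recent-RT, IDH, MGMT) are plain
        # row filters feeding the same evaluation
        from gliodx import CohortSpec, evaluate_parameter, simulate_cohort

        df = simulate_cohort(CohortSpec(seed=11))
        full = evaluate_parameter(df, "tbr_max")
        enh = evaluate_parameter(df[df["enhancing"]], "tbr_max")
        recent = evaluate_parameter(df[df["days_from_rt"] < 182], "tbr_max")
        for s in (full, enh, recent):
            assert 0.5 <= s.auc <= 1.0
            assert s.cutoff is not None
        assert enh.table.n == int(df["enhancing"].sum())


class TestPatientwise:
    def test_max_across_lesions(self):
        df = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2"],
                "tbr_max": [1.4, 2.9, 1.1],
                "outcome": ["non-progressive", "progressive", "non-progressive"],
            }
        )
        pw = patientwise_analysis(df, "tbr_max")
        assert pw.set_index("patient_id").loc["p1", "tbr_max"] == 2.9
        assert pw.set_index("patient_id").loc["p2", "tbr_max"] == 1.1  # pass-through

    def test_default_cohort_yields_59_evaluable_patients(self):
        from gliodx import CohortSpec, simulate_cohort

        df = simulate_cohort(CohortSpec(seed=0))
        pw = patientwise_analysis(df, "tbr_max")
        assert len(pw) == 59

    def test_lesions_without_outcome_still_contribute_scores(self):
        df = pd.DataFrame(
            {
                "patient_id": ["p1", "p1"],
                "tbr_max": [5.0, 1.0],
                "outcome": ["non-evaluable", "progressive"],
            }
        )
        pw = patientwise_analysis(df, "tbr_max")
        assert pw["tbr_max"].iloc[0] == 5.0
        assert pw["outcome"].iloc[0] == "progressive"
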