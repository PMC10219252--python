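import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fdscreen.evaluate import (
    ConfusionMatrix,
    compare_cohort_characteristics,
    confusion_at_cutoff,
    enrichment_ratio,
    evaluate_cohort,
    metrics,
    roc_pr_curves,
    sweep_cutoffs,
)

# scores and boolean labels for small random cohorts
cohorts = st.lists(
    st.tuples(st.integers(0, 12), st.booleans()), min_size=4, max_size=60
).filter(lambda rows: 0 < sum(lab for _, lab in rows) < len(rows))


# -- confusion matrix ---------------------------------------------------------


class TestConfusionAtCutoff:
    def test_perfect_separation_has_no_errors(self):
        cm = confusion_at_cutoff([9, 8, 1, 0], [True, True, False, False], 4)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)

    def test_reported_screening_cohort_counts(self):
        # 13 cases of whom 12 score >= 4; 19,372 controls of whom 80 score >= 4
        scores = [5] * 12 + [3] + [4] * 80 + [1] * 19292
        labels = [True] * 13 + [False] * 19372
        cm = confusion_at_cutoff(scores, labels, 4)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (12, 1, 80, 19292)

    def test_cutoff_zero_flags_everyone(self):
        cm = confusion_at_cutoff([0, 3, 7], [True, False, True], 0)
        assert cm.fn == 0 and cm.tn == 0

    def test_missing_label_raises(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1, 2], [True, None], 1)

    @settings(max_examples=80, derandomize=True)
    @given(cohorts, st.integers(0, 13))
    def test_matches_per_patient_recount(self, rows, cutoff):
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        cm = confusion_at_cutoff(scores, labels, cutoff)
        tp = sum(1 for s, l in rows if s >= cutoff and l)
        fp = sum(1 for s, l in rows if s >= cutoff and not l)
        tn = sum(1 for s, l in rows if s < cutoff and not l)
        fn = sum(1 for s, l in rows if s < cutoff and l)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
        assert cm.total == len(rows)


# -- derived metrics ----------------------------------------------------------


class TestMetrics:
    def test_screening_cohort_metric_values(self):
        m = metrics(ConfusionMatrix(tp=12, fp=80, tn=19292, fn=1))
        assert round(m.accuracy, 3) == 0.996
        assert round(m.recall * 100, 1) == 92.3
        assert round(m.specificity * 100, 2) == 99.59
        assert round(m.precision, 4) == 0.1304
        assert round(m.f1, 4) == 0.2286

    def test_perfect_tiny_matrix(self):
        m = metrics(ConfusionMatrix(tp=1, fp=0, tn=1, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.specificity, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_degenerate_no_true_positives(self):
        m = metrics(ConfusionMatrix(tp=0, fp=5, tn=10, fn=2))
        assert m.precision == 0.0
        assert math.isnan(m.f1) and "f1" in m.undefined


# -- cutoff sweep -------------------------------------------------------------


class TestSweepCutoffs:
    def test_sensitivity_one_at_minimum_case_score(self):
        # no case scores below 3, so a cut-off of 3 catches them all
        scores = [3, 5, 8, 1, 2, 6]
        labels = [True, True, True, False, False, False]
        table = sweep_cutoffs(scores, labels, (3, 11))
        assert table.loc[table.cutoff == 3, "sensitivity"].item() == 1.0

    def test_single_cutoff_row_is_consistent(self):
        scores, labels = [4, 1], [True, False]
        table = sweep_cutoffs(scores, labels, (4, 4))
        cm = confusion_at_cutoff(scores, labels, 4)
        row = table.iloc[0]
        assert (row.tp, row.fp, row.tn, row.fn) == (cm.tp, cm.fp, cm.tn, cm.fn)

    @settings(max_examples=80, derandomize=True)
    @given(cohorts)
    def test_monotone_in_cutoff(self, rows):
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        table = sweep_cutoffs(scores, labels, (0, 13))
        assert (np.diff(table.sensitivity) <= 1e-12).all()
        assert (np.diff(table.specificity) >= -1e-12).all()


# -- ROC / PR curves ----------------------------------------------------------


class TestRocPrCurves:
    def test_perfect_separation_gives_unit_areas(self):
        _, _, auc_roc, auc_pr = roc_pr_curves([5, 6, 1, 2], [True, True, False, False])
        assert auc_roc == pytest.approx(1.0)
        assert auc_pr == pytest.approx(1.0)

    def test_uninformative_scores_give_half_roc_area(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 10, size=10_000)
        labels = rng.random(10_000) < 0.3
        _, _, auc_roc, _ = roc_pr_curves(scores, labels)
        assert auc_roc == pytest.approx(0.5, abs=0.02)

    @settings(max_examples=80, derandomize=True)
    @given(cohorts)
    def test_roc_area_equals_normalized_mann_whitney_u(self, rows):
        scores = np.array([s for s, _ in rows], dtype=float)
        labels = np.array([l for _, l in rows])
        _, _, auc_roc, _ = roc_pr_curves(scores, labels)
        # rank-statistic oracle: P(case score > control score) + 0.5 P(equal)
        pos, neg = scores[labels], scores[~labels]
        u = sum((pos[:, None] > neg).sum() + 0.5 * (pos[:, None] == neg).sum()
                for _ in [0])
        assert auc_roc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(cohorts)
    def test_areas_match_sklearn_reference(self, rows):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        scores = [s for s, _ in rows]
        labels = [l for _, l in rows]
        _, _, auc_roc, auc_pr = roc_pr_curves(scores, labels)
        assert auc_roc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )
        assert auc_pr == pytest.approx(
            sklearn_metrics.average_precision_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 12, 200).astype(float)
        labels = rng.random(200) < 0.2
        _, _, auc1, _ = roc_pr_curves(scores, labels)
        _, _, auc2, _ = roc_pr_curves(np.exp(scores / 3.0), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_cohort_raises(self):
        with pytest.raises(ValueError):
            roc_pr_curves([1, 2, 3], [True, True, True])


# -- enrichment ---------------------------------------------------------------


class TestEnrichmentRatio:
    def test_screening_cohort_enrichment(self):
        r = enrichment_ratio(ConfusionMatrix(tp=12, fp=80, tn=0, fn=0), 40_000)
        assert r.ratio_k == 7
        assert int(r.fold) == 5714

    def test_equal_counts_give_population_fold(self):
        r = enrichment_ratio(ConfusionMatrix(tp=5, fp=5, tn=0, fn=0), 40_000)
        assert r.ratio_k == 1 and r.fold == 40_000

    def test_all_true_positive_flagged(self):
        r = enrichment_ratio(ConfusionMatrix(tp=10, fp=0, tn=0, fn=0), 40_000)
        assert r.ratio_k == 0 and r.flag == "all_true_positive"

    def test_no_true_positives_undefined(self):
        r = enrichment_ratio(ConfusionMatrix(tp=0, fp=3, tn=0, fn=0), 40_000)
        assert r.flag == "undefined" and r.ratio_k is None


# -- group comparisons --------------------------------------------------------


def _fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p-value."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, row1, col1)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestCompareCohortCharacteristics:
    def _frames(self, case_flags, ctrl_flags, case_ages=None, ctrl_ages=None):
        cases = pd.DataFrame(
            {"age": case_ages or [40 + i for i in range(len(case_flags))],
             "trait": case_flags}
        )
        controls = pd.DataFrame(
            {"age": ctrl_ages or [40 + i for i in range(len(ctrl_flags))],
             "trait": ctrl_flags}
        )
        return cases, controls

    def test_identical_groups_show_no_evidence(self):
        cases, controls = self._frames([1, 0, 1, 0] * 5, [1, 0, 1, 0] * 5)
        out = compare_cohort_characteristics(
            cases, controls, numeric=["age"], categorical=["trait"]
        )
        assert (out.p_value > 0.9).all()

    def test_zero_incidence_trait_is_untested(self):
        cases, controls = self._frames([0] * 8, [1, 0] * 4)
        out = compare_cohort_characteristics(
            cases, controls, numeric=[], categorical=["trait"]
        )
        row = out.iloc[0]
        assert not row.tested and math.isnan(row.p_value)

    def test_small_table_uses_fisher_and_matches_enumeration_oracle(self):
        case_flags = [1, 1, 1, 0, 0]
        ctrl_flags = [0, 0, 0, 0, 1, 0, 0, 1]
        cases, controls = self._frames(case_flags, ctrl_flags)
        out = compare_cohort_characteristics(
            cases, controls, numeric=[], categorical=["trait"]
        )
        row = out.iloc[0]
        assert row.test == "fisher-exact"
        table = [
            [sum(case_flags), len(case_flags) - sum(case_flags)],
            [sum(ctrl_flags), len(ctrl_flags) - sum(ctrl_flags)],
        ]
        assert row.p_value == pytest.approx(_fisher_two_sided_oracle(table), rel=1e-6)

    def test_large_balanced_table_uses_chi_squared(self):
        cases, controls = self._frames([1] * 30 + [0] * 30, [1] * 20 + [0] * 40)
        out = compare_cohort_characteristics(
            cases, controls, numeric=[], categorical=["trait"]
        )
        assert out.iloc[0].test == "chi-squared"


# -- whole-cohort evaluation --------------------------------------------------


def test_evaluate_cohort_bundles_consistent_pieces():
    scores = [5] * 12 + [3] + [4] * 80 + [1] * 1000
    labels = ["case"] * 13 + ["control"] * 1080
    ev = evaluate_cohort(scores, labels, cutoff=4)
    assert (ev.matrix.tp, ev.matrix.fn, ev.matrix.fp) == (12, 1, 80)
    assert ev.enrichment.ratio_k == 7
    assert len(ev.sweep) == 9  # cut-offs 3..11
    d = ev.as_dict()
    assert d["confusion_matrix"]["tp"] == 12
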