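"""Grouping, ROC/Youden, diagnostic metrics, correlation and odds ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from eusei import stratification as st
from eusei.errors import InvalidArgumentError, SeparationError, UngroupableError


class TestGrouping:
    @pytest.mark.parametrize(
        "nih,group",
        [
            ("very_low", "low_risk"),
            ("low", "low_risk"),
            ("intermediate", "high_risk"),
            ("high", "high_risk"),
        ],
    )
    def test_nih_collapse(self, nih, group):
        assert st.group_nih(nih) == group

    def test_study_category_counts_collapse_to_group_sizes(self):
        counts = {"very_low": 15, "low": 31, "intermediate": 29, "high": 9}
        groups = {"low_risk": 0, "high_risk": 0}
        for nih, k in counts.items():
            groups[st.group_nih(nih)] += k
        assert groups == {"low_risk": 46, "high_risk": 38}

    def test_unknown_category_is_ungroupable(self):
        with pytest.raises(UngroupableError):
            st.group_nih("unknown")


class TestClassify:
    def test_typical_group_medians_classified_correctly(self):
        assert st.classify(0.186, 0.224) == "high_risk"
        assert st.classify(0.268, 0.224) == "low_risk"

    def test_boundary_is_strict(self):
        assert st.classify(0.224, 0.224) == "low_risk"

    def test_missing_value_unclassifiable(self):
        with pytest.raises(InvalidArgumentError):
            st.classify(float("nan"), 0.224)


class TestConfusion:
    def test_all_correct_has_no_errors(self):
        cm = st.confusion([0.1, 0.1, 0.4, 0.4], ["high_risk"] * 2 + ["low_risk"] * 2, 0.224)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 0, 2, 0)

    def test_all_low_risk_below_cutoff_are_false_positives(self):
        cm = st.confusion([0.1] * 5, ["low_risk"] * 5, 0.224)
        assert (cm.tp, cm.tn, cm.fn, cm.fp) == (0, 0, 0, 5)

    def test_counts_conserve_n(self, rng):
        for _ in range(20):
            v = rng.random(25)
            lab = rng.random(25) < 0.4
            cm = st.confusion(v, lab, float(rng.random()))
            assert cm.n == 25


class TestDiagnosticMetrics:
    def test_small_lesion_subgroup_worked_example(self):
        # 27 low-risk / 4 high-risk patients at the published cutoff:
        # 3/4 sensitivity, 22/27 specificity -> accuracy 25/31
        cm = st.ConfusionMatrix(tp=3, fp=5, tn=22, fn=1)
        d = st.diagnostic_metrics(cm)
        assert round(d.accuracy.estimate, 2) == 80.65
        assert d.sensitivity.estimate == pytest.approx(75.0)
        assert round(d.sensitivity.lower, 1) == 32.6
        assert d.sensitivity.upper == 100.0  # Wald upper clamped
        assert round(d.specificity.estimate, 1) == 81.5

    def test_accuracy_identity(self):
        cm = st.ConfusionMatrix(tp=30, fp=4, tn=42, fn=8)
        d = st.diagnostic_metrics(cm)
        p, n = cm.tp + cm.fn, cm.tn + cm.fp
        acc = (d.sensitivity.estimate * p + d.specificity.estimate * n) / cm.n
        assert d.accuracy.estimate == pytest.approx(acc)

    def test_zero_denominator_metric_is_undefined(self):
        d = st.diagnostic_metrics(st.ConfusionMatrix(tp=0, fp=3, tn=7, fn=0))
        assert d.sensitivity is None
        assert d.specificity is not None

    def test_wilson_interval_available(self):
        d = st.diagnostic_metrics(st.ConfusionMatrix(3, 5, 22, 1), ci_method="wilson")
        assert 0 <= d.sensitivity.lower < 75 < d.sensitivity.upper <= 100
        with pytest.raises(InvalidArgumentError):
            st.diagnostic_metrics(st.ConfusionMatrix(3, 5, 22, 1), ci_method="bayes")


def random_dataset(rng, n=40):
    v = np.round(rng.random(n), 2)  # rounding forces ties
    lab = rng.random(n) < 0.45
    if lab.all() or not lab.any():
        lab[0] = ~lab[0]
    return v, lab


class TestRoc:
    def test_perfect_separation_auc_one(self):
        curve = st.roc([0.1, 0.15, 0.3, 0.35], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)

    def test_identical_distributions_auc_half(self):
        v = np.tile(np.linspace(0, 1, 10), 2)
        lab = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert st.roc(v, lab).auc == pytest.approx(0.5)

    def test_auc_equals_rank_statistic_on_seeded_datasets(self, rng):
        for _ in range(100):
            v, lab = random_dataset(rng)
            auc = st.roc(v, lab).auc
            u = mannwhitneyu(v[~lab], v[lab]).statistic / (lab.sum() * (~lab).sum())
            assert auc == pytest.approx(u, abs=1e-10)

    def test_flipping_labels_complements_auc(self, rng):
        v, lab = random_dataset(rng)
        assert st.roc(v, lab).auc + st.roc(v, ~lab).auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            st.roc([0.1, 0.2], [True, True])


def brute_force_youden(v, lab):
    """Exhaustive J maximization over the midpoint candidates (oracle)."""
    pos, neg = v[lab], v[~lab]
    distinct = np.unique(v)
    cands = np.concatenate([[-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]])
    best = None
    for c in cands:
        sens = (pos < c).mean()
        spec = (neg >= c).mean()
        key = (-(sens + spec - 1), -sens, c)
        if best is None or key < best:
            best = key
    return -best[0]


class TestYouden:
    def test_perfectly_separated_groups_midpoint_cutoff(self):
        curve = st.roc([0.1, 0.15, 0.3, 0.35], [True, True, False, False])
        cutoff, j = st.youden_cutoff(curve)
        assert cutoff == pytest.approx(0.225)
        assert j == pytest.approx(1.0)

    def test_matches_brute_force_on_seeded_datasets(self, rng):
        for _ in range(100):
            v, lab = random_dataset(rng)
            _, j = st.youden_cutoff(st.roc(v, lab))
            assert j == pytest.approx(brute_force_youden(v, lab), abs=1e-12)

    def test_orientation_swap_with_negated_values_preserves_j(self, rng):
        v, lab = random_dataset(rng)
        _, j = st.youden_cutoff(st.roc(v, lab))
        _, j_neg = st.youden_cutoff(st.roc(-v, ~lab))
        assert j == pytest.approx(j_neg, abs=1e-12)
        assert st.roc(-v, ~lab).auc == pytest.approx(st.roc(v, lab).auc, abs=1e-12)


class TestSpearman:
    def test_monotone_sequences(self):
        assert st.spearman([1, 2, 3, 5], [2, 4, 9, 11]) == pytest.approx(1.0)
        assert st.spearman([1, 2, 3, 5], [11, 9, 4, 2]) == pytest.approx(-1.0)

    def test_average_rank_tie_handling(self):
        assert st.spearman([1, 2, 2, 4], [1, 2, 3, 4]) == pytest.approx(0.9487, abs=1e-4)

    def test_constant_input_undefined(self):
        with pytest.raises(InvalidArgumentError):
            st.spearman([1, 1, 1], [1, 2, 3])


class TestLogisticOr:
    def test_univariable_binary_covariate_equals_sample_odds_ratio(self):
        # 2x2 counts a=10, b=5, c=2, d=8 -> OR = ad/bc = 8
        x = np.r_[np.ones(10), np.zeros(5), np.ones(2), np.zeros(8)]
        y = np.r_[np.ones(15), np.zeros(10)].astype(bool)
        table = st.logistic_or(pd.DataFrame({"exposure": x}), y)
        assert table.loc["exposure", "or_uni"] == pytest.approx(8.0, rel=1e-4)
        assert table.loc["exposure", "ci_low_uni"] < 8.0 < table.loc["exposure", "ci_high_uni"]

    def test_balanced_covariate_odds_ratio_one(self):
        x = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        y = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        table = st.logistic_or(pd.DataFrame({"exposure": x}), y)
        assert table.loc["exposure", "or_uni"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_outcome_is_separation(self):
        with pytest.raises(SeparationError):
            st.logistic_or(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [True, True, True])

    def test_separated_covariate_named(self):
        x = np.r_[np.ones(5) + 1, np.zeros(5)]
        y = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        with pytest.raises(SeparationError) as err:
            st.logistic_or(pd.DataFrame({"stiffness": x}), y)
        assert err.value.covariate == "stiffness"


class TestCohortSummary:
    def _records(self):
        rng = np.random.default_rng(0)
        n = 189
        return pd.DataFrame(
            {
                "sex": ["male"] * 92 + ["female"] * 97,
                "size_class": ["gt2cm"] * 108 + ["le2cm"] * 81,
                "age": rng.normal(57.6, 11.57, n),
                "eus_e_ai": rng.uniform(0.1, 0.5, n),
                "group": rng.choice(["low_risk", "high_risk"], n),
            }
        )

    def test_table_style_percentages(self):
        out = st.cohort_summary(self._records())
        assert out["size_class"]["overall"]["gt2cm"] == "108 (57.1%)"
        assert out["sex"]["overall"]["male"] == "92 (48.7%)"
        assert out["n"] == 189
        assert "p" in out["age"] and "p" in out["eus_e_ai"]

    def test_single_record_has_no_tests(self):
        df = self._records().iloc[:1]
        out = st.cohort_summary(df)
        assert out["sex"]["overall"]["male"] == "1 (100.0%)"
        assert "p" not in out["sex"]

    def test_fisher_used_for_sparse_2x2(self):
        df = pd.DataFrame(
            {
                "sex": ["male"] * 3 + ["female"] * 17,
                "group": ["high_risk"] * 10 + ["low_risk"] * 10,
            }
        )
        out = st.cohort_summary(df, categorical=("sex",), normal=(), nonnormal=())
        assert out["sex"]["test"] == "fisher"
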