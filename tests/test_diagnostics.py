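"""ROC/AUC machinery, cutoff metric tables and predictive-value algebra."""

import math

import numpy as np
import pytest

from coldstun_mpi import (
    CohortError,
    ConfusionMatrix,
    CutoffRow,
    ScoredCohort,
    auc,
    auc_ci,
    confusion_at_cutoff,
    cutoff_table,
    load_reference_performance,
    optimal_cutoff,
    per_analyte_auc,
    analyte_retention,
    predictive_values_at_prevalence,
    prevalence_curve,
    roc_curve,
)
from coldstun_mpi import test_metrics as metrics_from_counts  # avoid pytest collection
from conftest import mann_whitney_auc, random_cohort


class TestConfusion:
    def test_enumerated_four_animal_cohort(self, four_animal_cohort):
        cm = confusion_at_cutoff(four_animal_cohort, 8)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_extreme_cutoffs(self, four_animal_cohort):
        low = confusion_at_cutoff(four_animal_cohort, -math.inf)
        assert low.fn == 0 and low.tn == 0
        high = confusion_at_cutoff(four_animal_cohort, 13)
        assert high.tp == 0 and high.fp == 0

    def test_counts_conserved(self, four_animal_cohort):
        for c in range(0, 14):
            cm = confusion_at_cutoff(four_animal_cohort, c)
            assert cm.n_pos == 2 and cm.n_neg == 2


class TestMetrics:
    def test_published_style_row(self):
        row = metrics_from_counts(ConfusionMatrix(tp=22, fn=3, tn=95, fp=23))
        assert row.se == pytest.approx(88.00)
        assert row.sp == pytest.approx(80.51, abs=0.005)
        assert row.ppv == pytest.approx(48.9, abs=0.05)
        assert row.npv == pytest.approx(96.9, abs=0.05)
        assert row.lr_plus == pytest.approx(4.51, abs=0.005)
        assert row.lr_minus == pytest.approx(0.15, abs=0.005)

    def test_second_published_style_row(self):
        row = metrics_from_counts(ConfusionMatrix(tp=17, fn=8, tn=103, fp=15))
        assert row.ppv == pytest.approx(53.1, abs=0.05)
        assert row.npv == pytest.approx(92.8, abs=0.05)
        assert row.lr_plus == pytest.approx(5.35, abs=0.005)
        assert row.lr_minus == pytest.approx(0.37, abs=0.005)

    def test_perfect_test(self):
        row = metrics_from_counts(ConfusionMatrix(tp=25, fn=0, tn=118, fp=0))
        assert (row.se, row.sp, row.ppv, row.npv) == (100.0, 100.0, 100.0, 100.0)
        assert row.lr_plus == math.inf
        assert row.lr_minus == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(CohortError):
            metrics_from_counts(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))

    def test_lr_and_bayes_identities_random_matrices(self):
        """LR+ = SE/(1-SP), LR- = (1-SE)/SP; PPV/NPV from counts equal the
        Bayes formulas evaluated at the cohort's own prevalence."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            tp, fn, tn, fp = (int(x) for x in rng.integers(0, 60, size=4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            cm = ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)
            row = metrics_from_counts(cm)
            se, sp = row.se / 100, row.sp / 100
            if sp < 1:
                assert row.lr_plus == pytest.approx(se / (1 - sp), rel=1e-12)
            if sp > 0:
                assert row.lr_minus == pytest.approx((1 - se) / sp, rel=1e-12)
            p = cm.n_pos / (cm.n_pos + cm.n_neg)
            ppv, npv = predictive_values_at_prevalence(se, sp, p)
            if not math.isnan(row.ppv):
                assert row.ppv == pytest.approx(100 * ppv, abs=1e-9)
            if not math.isnan(row.npv):
                assert row.npv == pytest.approx(100 * npv, abs=1e-9)


class TestCutoffTable:
    def test_single_cutoff_matches_composition(self, four_animal_cohort):
        [row] = cutoff_table(four_animal_cohort, [8])
        assert row == metrics_from_counts(confusion_at_cutoff(four_animal_cohort, 8), 8.0)

    def test_se_monotone_and_extremes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cohort = random_cohort(rng)
            rows = cutoff_table(cohort)
            ses = [r.se for r in rows]
            sps = [r.sp for r in rows]
            assert ses == sorted(ses, reverse=True)
            assert sps == sorted(sps)
        # spanning grid: everything positive at the low end, nothing at the top
        cohort = ScoredCohort.from_pairs([(5, 1), (6, 1), (1, 0), (2, 0)])
        rows = cutoff_table(cohort, [0, 7])
        assert rows[0].se == 100.0 and rows[-1].se == 0.0


class TestROC:
    def test_brute_force_pair_example(self):
        cohort = ScoredCohort.from_pairs([(3, 1), (5, 1), (1, 0), (4, 0)])
        assert roc_curve(cohort).auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        cohort = ScoredCohort.from_pairs([(10, 1), (11, 1), (1, 0), (2, 0)])
        assert roc_curve(cohort).auc == pytest.approx(1.0)

    def test_complete_tie_is_degenerate_half(self):
        cohort = ScoredCohort.from_pairs([(2, 1), (2, 0)])
        res = roc_curve(cohort)
        assert res.auc == pytest.approx(0.5)
        assert len(res.fpr) == 2  # (0,0) and (1,1) only

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            cohort = random_cohort(rng, max_n=60)
            expected = mann_whitney_auc(cohort)
            assert roc_curve(cohort).auc == pytest.approx(expected, abs=1e-12)
            assert auc(cohort) == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_learn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(10):
            cohort = random_cohort(rng)
            assert roc_curve(cohort).auc == pytest.approx(
                roc_auc_score(cohort.outcomes, cohort.scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        cohort = random_cohort(rng)
        transformed = ScoredCohort(np.exp(cohort.scores / 4.0) + 7, cohort.outcomes)
        assert auc(transformed) == pytest.approx(auc(cohort), abs=1e-12)

    def test_operating_points_monotone(self):
        rng = np.random.default_rng(13)
        res = roc_curve(random_cohort(rng))
        assert (np.diff(res.fpr) >= 0).all()
        assert (np.diff(res.tpr) >= 0).all()


class TestAUCCI:
    def test_interval_brackets_auc_and_narrows(self):
        rng = np.random.default_rng(21)
        for n in (20, 200):
            pos = rng.normal(2.0, 1.0, n)
            neg = rng.normal(0.0, 1.0, n)
            cohort = ScoredCohort(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones(n, int), np.zeros(n, int)]),
            )
            a = auc(cohort)
            lo, hi = auc_ci(cohort, "delong")
            assert lo <= a <= hi
            if n == 20:
                wide = hi - lo
            else:
                assert hi - lo < wide

    def test_methods_agree_on_moderate_cohort(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(1.5, 1.0, 120)
        neg = rng.normal(0.0, 1.0, 200)
        cohort = ScoredCohort(
            np.concatenate([pos, neg]),
            np.concatenate([np.ones(120, int), np.zeros(200, int)]),
        )
        dlo, dhi = auc_ci(cohort, "delong")
        blo, bhi = auc_ci(cohort, "bootstrap", seed=99, n_boot=2000)
        hlo, hhi = auc_ci(cohort, "hanley-mcneil")
        assert dlo == pytest.approx(blo, abs=0.02)
        assert dhi == pytest.approx(bhi, abs=0.02)
        assert dlo == pytest.approx(hlo, abs=0.03)
        assert dhi == pytest.approx(hhi, abs=0.03)

    def test_bootstrap_reproducible_under_seed(self, four_animal_cohort):
        a = auc_ci(four_animal_cohort, "bootstrap", seed=1, n_boot=200)
        b = auc_ci(four_animal_cohort, "bootstrap", seed=1, n_boot=200)
        assert a == b

    def test_unsupported_method_rejected(self, four_animal_cohort):
        from coldstun_mpi import ConfigurationError

        with pytest.raises(ConfigurationError):
            auc_ci(four_animal_cohort, "medcalc")


class TestCutoffSelection:
    def test_published_rows_recover_bold_cutoffs(self):
        ref = load_reference_performance()
        expected = {"MPI4": 10, "MPI5": 6, "MPI6": 8}
        for name, table in ref["tables"].items():
            rows = [
                CutoffRow(r["cutoff"], r["se"], r["sp"], r["ppv"], r["npv"],
                          r["lr_plus"], r["lr_minus"])
                for r in table["rows"]
            ]
            assert optimal_cutoff(rows) == expected[name]
            assert table["optimal_cutoff"] == expected[name]

    def test_single_row_and_tie_break(self):
        one = CutoffRow(5, 80, 80, 50, 95, 4, 0.25)
        assert optimal_cutoff([one]) == 5
        tie = [CutoffRow(4, 90, 70, 0, 0, 0, 0), CutoffRow(6, 70, 90, 0, 0, 0, 0)]
        assert optimal_cutoff(tie) == 4  # equal J: lower cutoff (higher SE) wins


class TestRetention:
    @pytest.mark.parametrize(
        "value,kept", [(0.70, True), (0.696, False), (1.0, True), (0.699999, False)]
    )
    def test_threshold_boundary(self, value, kept):
        assert analyte_retention(value) is kept

    def test_per_analyte_screening_separates_informative_analyte(self, tables):
        # potassium deranged only in non-survivors: retained; glucose pure noise
        from coldstun_mpi import BloodPanel

        rng = np.random.default_rng(17)
        panels = []
        for i in range(300):
            died = i < 60
            panels.append(
                BloodPanel(
                    animal_id=f"p{i}",
                    potassium=float(rng.uniform(6.0, 9.0) if died else rng.uniform(3.0, 4.4)),
                    glucose=float(rng.uniform(0.5, 20.0)),
                    outcome=int(died),
                )
            )
        aucs = per_analyte_auc(panels, "MPI3", analytes=("potassium", "glucose"))
        assert analyte_retention(aucs["potassium"])
        assert not analyte_retention(aucs["glucose"])


class TestPredictiveValues:
    def test_study_prevalence_cross_check(self):
        ppv, npv = predictive_values_at_prevalence(0.88, 0.805, 25 / 143)
        assert ppv == pytest.approx(0.489, abs=0.005)
        assert npv == pytest.approx(0.969, abs=0.005)

    def test_zero_prevalence(self):
        ppv, npv = predictive_values_at_prevalence(0.9, 0.8, 0.0)
        assert ppv == 0.0 and npv == 1.0
        ppv, npv = predictive_values_at_prevalence(0.9, 1.0, 0.0)
        assert math.isnan(ppv) and npv == 1.0

    def test_high_mortality_scenario(self):
        ppv, _ = predictive_values_at_prevalence(0.88, 0.80, 0.40)
        assert ppv == pytest.approx(0.7458, abs=1e-4)

    def test_curve_monotone_in_prevalence(self):
        rows = prevalence_curve(0.88, 0.805, 0.10, 0.40, 0.01)
        ps = [r[0] for r in rows]
        ppvs = [r[1] for r in rows]
        npvs = [r[2] for r in rows]
        assert ps[0] == pytest.approx(0.10) and ps[-1] == pytest.approx(0.40)
        assert ppvs == sorted(ppvs)
        assert npvs == sorted(npvs, reverse=True)
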