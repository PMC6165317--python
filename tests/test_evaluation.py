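"""Matching-rate arithmetic, reliability, LPOCV, and report rendering."""

import io
from itertools import combinations

import numpy as np
import pytest

from shadematch.errors import ValidationError
from shadematch.evaluation import (
    EvaluationReport,
    LPOCVResult,
    failure_rate,
    lpocv,
    matching_rate,
    reliability,
    report_table,
    summarize_runs,
)
from shadematch.shade_db import TAB_LABELS

# published-style per-run rates for two example device rows (percent, one
# decimal); both are exact multiples of 100/26 after snapping
SVM_DEV1_RATES = [96.2, 92.3, 100.0, 88.5, 88.5, 100.0, 100.0, 96.2, 96.2, 92.3]
DE_DEV1_RATES = [84.6, 96.2, 100.0, 80.8, 88.5, 88.5, 80.8, 88.5, 88.5, 84.6]


class TestMatchingRate:
    def test_half_matched_is_fifty_percent(self):
        preds = {t: t for t in TAB_LABELS[:13]}
        preds.update({t: "1M1" if t != "1M1" else "1M2" for t in TAB_LABELS[13:]})
        assert matching_rate(preds).exact == pytest.approx(50.0)

    def test_perfect_and_single_miss(self):
        perfect = {t: t for t in TAB_LABELS}
        assert matching_rate(perfect) == (100.0, 100.0)
        one_off = dict(perfect, **{"5M3": "5M2"})
        rate = matching_rate(one_off)
        assert rate.exact == pytest.approx(100 * 25 / 26)
        assert rate.rounded == 96.2

    def test_missing_tab_rejected(self):
        preds = {t: t for t in TAB_LABELS[:-1]}
        with pytest.raises(ValidationError):
            matching_rate(preds)

    def test_rates_live_on_the_26th_grid(self, identity_db):
        # any full-guide run rate is k/26 * 100
        from shadematch.matching import match_euclidean

        preds = {
            t: match_euclidean(identity_db.representatives[t], identity_db).predicted
            for t in TAB_LABELS
        }
        rate = matching_rate(preds).exact
        assert (rate * 26 / 100) == pytest.approx(round(rate * 26 / 100))


class TestSummarizeRuns:
    def test_reproduces_published_svm_row(self):
        mean, sd = summarize_runs(SVM_DEV1_RATES)
        assert mean == 95.0
        assert round(sd, 2) == 4.46

    def test_reproduces_published_euclidean_row(self):
        mean, sd = summarize_runs(DE_DEV1_RATES)
        assert mean == 88.1
        assert round(sd, 1) == 6.1

    def test_snapping_distinguishes_the_sd_conventions(self):
        # SD on the one-decimal values instead of the exact fractions
        # rounds to 4.45, not 4.46 — the snap restores the fractions
        sd_rounded = float(np.std(SVM_DEV1_RATES, ddof=1))
        assert round(sd_rounded, 2) == 4.45
        _, sd_snapped = summarize_runs(SVM_DEV1_RATES)
        assert round(sd_snapped, 2) == 4.46

    def test_constant_rates_have_zero_sd(self):
        assert summarize_runs([88.5] * 5)[1] == 0.0

    def test_fewer_than_two_rates_rejected(self):
        with pytest.raises(ValidationError):
            summarize_runs([96.2])


class TestReliability:
    def test_unanimous_predictions_are_fully_reliable_even_if_wrong(self):
        per_tab, overall = reliability({"1M1": ["2M2"] * 10})
        assert per_tab["1M1"] == 100.0 and overall == 100.0

    def test_modal_frequency(self):
        per_tab, _ = reliability({"1M1": ["1M1"] * 9 + ["1M2"]})
        assert per_tab["1M1"] == 90.0

    def test_even_split_is_half_reliable(self):
        per_tab, _ = reliability({"1M1": ["1M1"] * 5 + ["1M2"] * 5})
        assert per_tab["1M1"] == 50.0

    def test_invariant_to_consistent_relabeling(self):
        preds = {"1M1": ["1M1", "1M1", "1M2"], "1M2": ["1M2"] * 3}
        relabeled = {
            tab: [{"1M1": "5M3", "1M2": "5M2"}[p] for p in ps]
            for tab, ps in preds.items()
        }
        assert reliability(preds)[1] == reliability(relabeled)[1]

    def test_empty_prediction_list_rejected(self):
        with pytest.raises(ValidationError):
            reliability({"1M1": []})

    def test_failure_rate_modes(self):
        preds = {
            "1M1": ["1M1"] * 8 + ["1M2"] * 2,
            "1M2": ["1M2"] * 10,
            "2M1": ["2M1"] * 6 + ["2M2"] * 4,
        }
        fr_tab = failure_rate(preds, mode="tab")
        assert fr_tab == pytest.approx(float(np.std([80, 100, 60], ddof=1)))
        fr_run = failure_rate(preds, mode="run")
        assert fr_run >= 0
        with pytest.raises(ValidationError):
            failure_rate(preds, mode="bogus")


class TestLpocv:
    def test_enumerates_all_56_splits_with_balanced_validation(self, noisy_family):
        result = lpocv(noisy_family["datasets"], p=3, algorithm="euclidean")
        assert result.split_count == 56
        assert set(result.per_device_counts.values()) == {21}
        assert sorted(result.validation_members) == sorted(
            combinations(sorted(noisy_family["datasets"]), 3)
        )

    def test_degenerate_p_rejected(self, noisy_family):
        for bad_p in (0, 8, 9):
            with pytest.raises(ValidationError):
                lpocv(noisy_family["datasets"], p=bad_p, algorithm="euclidean")

    def test_accuracy_invariant_to_dataset_order(self, noisy_family):
        datasets = noisy_family["datasets"]
        fwd = lpocv(datasets, p=2, algorithm="euclidean")
        shuffled = dict(reversed(list(datasets.items())))
        rev = lpocv(shuffled, p=2, algorithm="euclidean")
        assert fwd.mean_accuracy == pytest.approx(rev.mean_accuracy)
        assert fwd.sd_accuracy == pytest.approx(rev.sd_accuracy)

    def test_classifier_route_runs(self, noisy_family):
        small = {k: noisy_family["datasets"][k] for k in list(noisy_family["datasets"])[:4]}
        result = lpocv(small, p=1, algorithm="knn", seed=0)
        assert result.split_count == 4
        assert 0 <= result.mean_accuracy <= 100


class TestReportTable:
    @staticmethod
    def _report():
        return EvaluationReport(
            device_id=1,
            method="svm",
            run_rates=SVM_DEV1_RATES,
            mean_rate=95.0,
            sd_rate=4.4596,
            per_tab_reliability={},
            overall_reliability=95.0,
            failure_rate_run=0.4,
            failure_rate_tab=1.0,
        )

    def test_empty_results_give_header_only(self):
        text, csv_text = report_table([], kind="runs")
        assert len(csv_text.splitlines()) == 1
        assert "Average" in text

    def test_known_fixture_renders_exactly(self):
        _, csv_text = report_table([self._report()], kind="runs")
        assert csv_text.splitlines()[1] == (
            "svm,#1,96.2,92.3,100.0,88.5,88.5,100.0,100.0,96.2,96.2,92.3,95.0,4.46"
        )

    def test_csv_reparses_to_the_same_numbers(self):
        import pandas as pd

        _, csv_text = report_table([self._report()], kind="runs")
        frame = pd.read_csv(io.StringIO(csv_text))
        assert frame["Average"].iloc[0] == 95.0
        assert frame["SD"].iloc[0] == 4.46

    def test_lpocv_table(self):
        result = LPOCVResult(
            p=3, algorithm="svm", split_count=56,
            per_split_accuracy=[], validation_members=[],
            mean_accuracy=96.9, sd_accuracy=1.37,
        )
        _, csv_text = report_table([result], kind="lpocv")
        assert csv_text.splitlines()[1] == "svm,96.9,1.37,56"
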