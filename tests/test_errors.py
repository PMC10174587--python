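import logging

import numpy as np
import pandas as pd
import pytest

from volcert import errors
from volcert.errors import (
    error_table,
    inter_operator_summary,
    inter_view_summary,
    intra_operator_summary,
    percent_error_profile,
)
from volcert.reference import recomputed_error_columns


def records_from(rows):
    return pd.DataFrame(rows, columns=["subject", "operator", "view",
                                       "repeat", "volume_ml"])


GOLD = pd.DataFrame({"subject": ["s1"], "volume_ml": [10.0]})


def repeats_records(volumes, operator="op1", view="axial", subject="s1"):
    return records_from(
        [(subject, operator, view, i + 1, v) for i, v in enumerate(volumes)]
    )


class TestIntraOperator:
    def test_hand_example(self):
        table = intra_operator_summary(repeats_records([10.0, 12.0, 14.0]), GOLD)
        row = table.iloc[0]
        assert row["mean_ml"] == pytest.approx(12.0)
        assert row["abs_error_ml"] == pytest.approx(2.0)
        assert row["n"] == 3

    def test_repeats_equal_to_gold_give_zero_error(self):
        table = intra_operator_summary(repeats_records([10.0, 10.0, 10.0]), GOLD)
        assert table["abs_error_ml"].iloc[0] == 0.0

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            intra_operator_summary(repeats_records([10.0]), GOLD)


class TestInterOperator:
    def make(self, op_volumes):
        rows = []
        for op, vols in op_volumes.items():
            rows += [("s1", op, "axial", i + 1, v) for i, v in enumerate(vols)]
        return records_from(rows)

    def test_mean_of_operator_means(self):
        rec = self.make({"a": [13.0, 13.0], "b": [14.0, 14.0]})
        row = inter_operator_summary(rec, GOLD).iloc[0]
        assert row["mean_ml"] == pytest.approx(13.5)
        assert row["abs_error_ml"] == pytest.approx(3.5)
        assert row["n"] == 2

    def test_operator_at_current_mean_leaves_summary_unchanged(self):
        rec = self.make({"a": [13.0], "b": [14.0]})
        extended = self.make({"a": [13.0], "b": [14.0], "c": [13.5]})
        before = inter_operator_summary(rec, GOLD).iloc[0]
        after = inter_operator_summary(extended, GOLD).iloc[0]
        assert after["mean_ml"] == pytest.approx(before["mean_ml"])
        assert after["abs_error_ml"] == pytest.approx(before["abs_error_ml"])

    def test_permutation_invariance(self):
        rec = self.make({"a": [13.0, 12.0], "b": [14.0, 15.0]})
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t0 = inter_operator_summary(rec, GOLD)
        t1 = inter_operator_summary(shuffled, GOLD)
        assert t0["mean_ml"].iloc[0] == pytest.approx(t1["mean_ml"].iloc[0])

    def test_single_operator_rejected(self):
        with pytest.raises(ValueError):
            inter_operator_summary(self.make({"a": [13.0]}), GOLD)

    def test_unsigned_error_but_signed_retained(self):
        rec = self.make({"a": [8.0, 8.0], "b": [9.0, 9.0]})  # mean below gold
        row = inter_operator_summary(rec, GOLD).iloc[0]
        assert row["abs_error_ml"] == pytest.approx(1.5)
        assert row["signed_error_ml"] == pytest.approx(-1.5)


class TestInterView:
    def make(self):
        rows = []
        for view, vol in (("axial", 8.0), ("coronal", 9.0), ("sagittal", 13.0)):
            rows += [("s1", "op1", view, r + 1, vol) for r in range(2)]
        return records_from(rows)

    def test_pooled_view_mean(self):
        row = inter_view_summary(self.make(), GOLD).iloc[0]
        assert row["mean_ml"] == pytest.approx(10.0)
        assert row["abs_error_ml"] == pytest.approx(0.0, abs=1e-9)
        assert row["n"] == 3

    def test_per_view_rows(self):
        table = inter_view_summary(self.make(), GOLD, per_view=True)
        assert set(table["view"]) == {"axial", "coronal", "sagittal"}
        sag = table[table["view"] == "sagittal"].iloc[0]
        assert sag["abs_error_ml"] == pytest.approx(3.0)

    def test_single_view_rejected(self):
        rec = repeats_records([10.0, 11.0])
        with pytest.raises(ValueError):
            inter_view_summary(rec, GOLD)


class TestHygiene:
    def test_duplicate_record_keys_rejected(self):
        rec = records_from([("s1", "a", "axial", 1, 10.0),
                            ("s1", "a", "axial", 1, 11.0)])
        with pytest.raises(ValueError, match="duplicate"):
            intra_operator_summary(rec, GOLD)

    def test_subject_without_gold_excluded_with_notice(self, caplog):
        rec = pd.concat([
            repeats_records([10.0, 12.0], subject="s1"),
            repeats_records([5.0, 6.0], subject="ghost"),
        ])
        with caplog.at_level(logging.WARNING, logger="volcert.errors"):
            table = intra_operator_summary(rec, GOLD)
        assert list(table["subject"]) == ["s1"]
        assert "ghost" in caplog.text

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            intra_operator_summary(repeats_records([-1.0, 2.0]), GOLD)


class TestPercentProfile:
    def test_percent_errors_and_maxima(self):
        table = pd.DataFrame({
            "subject": ["a", "b", "a", "b"],
            "experiment": ["inter_op", "inter_op", "intra_op", "intra_op"],
            "percent_error": [31.84, 10.0, 5.0, 48.0],
        })
        pivot, maxima = percent_error_profile(table)
        assert pivot.loc["a", "inter_op"] == 31.84
        assert maxima == {"inter_op": 31.84, "intra_op": 48.0}

    def test_requires_percent_column(self):
        with pytest.raises(ValueError):
            percent_error_profile(pd.DataFrame({"subject": []}))


class TestStudyRecordArithmetic:
    """Recompute the operator study's error columns from its own inputs."""

    def test_error_columns_recompute_within_printed_rounding(self):
        audit = recomputed_error_columns()
        diff = (audit["recomputed_error_ml"] - audit["error_ml"]).abs()
        assert len(audit) == 33
        assert (diff <= 0.1 + 1e-9).all()

    def test_error_table_pipeline_on_simulated_study(self):
        from volcert import phantom

        subjects = {
            lab: phantom.voxelize(
                phantom.ventricle_phantom(target_volume_ml=v, seed=i), 1.5
            )
            for i, (lab, v) in enumerate([("a", 8.0), ("b", 20.0)])
        }
        records, gold = phantom.simulate_study(subjects, n_repeats=2)
        table = error_table(records, gold)
        assert set(table["experiment"]) == set(errors.EXPERIMENTS)
        assert (table["percent_error"] >= 0).all()
        # positive operator bias: manual means exceed the gold standard
        assert (table["signed_error_ml"] > 0).all()
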