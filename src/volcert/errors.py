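"""Human manual-segmentation error summaries.

Given a long table of operator readings (subject, operator, view, repeat,
volume_ml) and per-subject gold-standard volumes, three experiment summaries
are computed, mirroring the study design:

* inter-operator — axial view; each operator contributes the mean of their
  repeats; the subject mean is the mean of those per-operator means (n =
  number of operators);
* inter-view — per-view means over all operators and repeats, pooled into a
  subject mean across the views (n = number of views);
* intra-operator — axial view; per-repeat-index means pooled across
  operators (n = number of repeats).

Errors are reported as absolute |mean - gold| (the study table is
unsigned); the signed difference is retained in a separate column.
Dispersion is the standard deviation across the n units of each experiment.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPERIMENTS = ("inter_op", "inter_view", "intra_op")

RECORD_COLUMNS = ("subject", "operator", "view", "repeat", "volume_ml")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table is missing columns {missing}")
    if (records["volume_ml"] < 0).any():
        raise ValueError("record volumes must be >= 0")
    dup = records.duplicated(subset=["subject", "operator", "view", "repeat"])
    if dup.any():
        raise ValueError(
            "duplicate (subject, operator, view, repeat) records: "
            f"{records.loc[dup, ['subject', 'operator', 'view', 'repeat']].values.tolist()}"
        )
    return records


def _gold_series(gold) -> pd.Series:
    if isinstance(gold, pd.DataFrame):
        return gold.set_index("subject")["volume_ml"].astype(float)
    return pd.Series(gold, dtype=float)


def _finish(per_subject: pd.DataFrame, gold: pd.Series, experiment: str) -> pd.DataFrame:
    known = per_subject["subject"].isin(gold.index)
    if not known.all():
        dropped = per_subject.loc[~known, "subject"].tolist()
        logger.warning("subjects without gold standard excluded: %s", dropped)
        per_subject = per_subject.loc[known]
    out = per_subject.copy()
    g = gold.loc[out["subject"]].to_numpy()
    out["gold_ml"] = g
    out["signed_error_ml"] = out["mean_ml"] - g
    out["abs_error_ml"] = out["signed_error_ml"].abs()
    out["percent_error"] = (100.0 * out["abs_error_ml"] / g).round(2)
    out.insert(1, "experiment", experiment)
    return out.reset_index(drop=True)


def _warn_missing(gold: pd.Series, present: Iterable[str]) -> None:
    missing = sorted(set(gold.index) - set(present))
    if missing:
        logger.warning("subjects with no records excluded: %s", missing)


def inter_operator_summary(
    records: pd.DataFrame, gold, view: str = "axial"
) -> pd.DataFrame:
    """Per-subject mean of per-operator mean volumes in one view."""
    records = _validate_records(records)
    gold = _gold_series(gold)
    sub = records[records["view"] == view]
    if sub.empty:
        raise ValueError(f"no records in view {view!r}")
    per_op = (
        sub.groupby(["subject", "operator"], sort=False)["volume_ml"]
        .mean()
        .reset_index()
    )
    agg = per_op.groupby("subject", sort=False)["volume_ml"].agg(
        mean_ml="mean", sd_ml="std", n="size"
    ).reset_index()
    if (agg["n"] < 2).any():
        raise ValueError("inter-operator summary needs >= 2 operators per subject")
    _warn_missing(gold, agg["subject"])
    return _finish(agg, gold, "inter_op")


def inter_view_summary(
    records: pd.DataFrame, gold, per_view: bool = False
) -> pd.DataFrame:
    """Pooled-view summary (or per-view rows with ``per_view=True``)."""
    records = _validate_records(records)
    gold = _gold_series(gold)
    views_present = records["view"].nunique()
    if views_present < 2:
        raise ValueError("inter-view summary needs records in >= 2 views")
    by_view = (
        records.groupby(["subject", "view"], sort=False)["volume_ml"]
        .mean()
        .reset_index()
    )
    if per_view:
        out = by_view.rename(columns={"volume_ml": "mean_ml"}).copy()
        out["sd_ml"] = np.nan
        out["n"] = 1
        g = gold.reindex(out["subject"])
        keep = g.notna().to_numpy()
        out = out.loc[keep].copy()
        g = g.dropna().to_numpy()
        out["gold_ml"] = g
        out["signed_error_ml"] = out["mean_ml"] - g
        out["abs_error_ml"] = out["signed_error_ml"].abs()
        out["percent_error"] = (100.0 * out["abs_error_ml"] / g).round(2)
        out.insert(1, "experiment", "inter_view")
        return out.reset_index(drop=True)
    agg = by_view.groupby("subject", sort=False)["volume_ml"].agg(
        mean_ml="mean", sd_ml="std", n="size"
    ).reset_index()
    _warn_missing(gold, agg["subject"])
    return _finish(agg, gold, "inter_view")


def intra_operator_summary(
    records: pd.DataFrame, gold, view: str = "axial"
) -> pd.DataFrame:
    """Per-subject mean over repeat indices (pooled across operators)."""
    records = _validate_records(records)
    gold = _gold_series(gold)
    sub = records[records["view"] == view]
    if sub.empty:
        raise ValueError(f"no records in view {view!r}")
    per_repeat = (
        sub.groupby(["subject", "repeat"], sort=False)["volume_ml"]
        .mean()
        .reset_index()
    )
    agg = per_repeat.groupby("subject", sort=False)["volume_ml"].agg(
        mean_ml="mean", sd_ml="std", n="size"
    ).reset_index()
    if (agg["n"] < 2).any():
        raise ValueError("intra-operator summary needs >= 2 repeats per subject")
    _warn_missing(gold, agg["subject"])
    return _finish(agg, gold, "intra_op")


def error_table(records: pd.DataFrame, gold) -> pd.DataFrame:
    """All three experiment summaries stacked into one table."""
    return pd.concat(
        [
            inter_operator_summary(records, gold),
            inter_view_summary(records, gold),
            intra_operator_summary(records, gold),
        ],
        ignore_index=True,
    )


def percent_error_profile(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-subject percent errors by experiment, plus per-experiment maxima.

    Returns the subject x experiment pivot of ``percent_error`` and a dict
    mapping each experiment to its worst percent error (the "errors up to
    X%" figures).
    """
    required = {"subject", "experiment", "percent_error"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    pivot = table.pivot_table(
        index="subject", columns="experiment", values="percent_error",
        aggfunc="max", sort=False,
    )
    maxima = {
        exp: float(grp["percent_error"].max())
        for exp, grp in table.groupby("experiment", sort=False)
    }
    return pivot, maxima


__all__ = [
    "EXPERIMENTS", "RECORD_COLUMNS", "inter_operator_summary",
    "inter_view_summary", "intra_operator_summary", "error_table",
    "percent_error_profile",
]
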