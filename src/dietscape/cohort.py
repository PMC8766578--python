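"""Aggregation of labeled food-log entries to participant and zip level.

Aggregation proceeds in the study's three stages: within participant-day
(daily counts per category), across active days within participant
(mean daily entries), then across participants within zip code
(unweighted mean of participant rates, plus the fraction with BMI > 25).

An *active day* is a calendar date on which the participant logged at
least one entry of any kind; days with no logging are excluded from the
rate denominator. Participants with fewer than ``min_days`` active days
and zip codes with fewer than ``min_participants`` retained participants
are dropped, mirroring the study's inclusion filters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_FLAGS",
    "participant_rates",
    "attach_participants",
    "filter_participants",
    "zip_outcomes",
]

log = logging.getLogger(__name__)

CATEGORY_FLAGS = ("is_fv", "is_fastfood", "is_soda")
RATE_COLUMNS = ("rate_fv", "rate_fastfood", "rate_soda")


def participant_rates(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-participant active-day counts and mean daily category rates.

    Parameters
    ----------
    labeled
        Entry table with ``participant_id``, ``log_date`` and the three
        boolean category flags (output of
        :func:`dietscape.classify.classify_entries`). All entries count
        toward activity, including those matching no category.

    Returns
    -------
    One row per participant: ``participant_id``, ``active_days``,
    ``rate_fv``, ``rate_fastfood``, ``rate_soda``. The rate for
    category *c* is (total entries flagged *c*) / (active days), i.e.
    the mean of the participant's daily counts over active days.
    """
    if labeled.empty:
        raise ValueError("no entries supplied")
    g = labeled.groupby("participant_id", sort=False)
    active = g["log_date"].nunique()
    totals = g[list(CATEGORY_FLAGS)].sum()
    rates = totals.div(active, axis=0)
    rates.columns = list(RATE_COLUMNS)
    out = rates.reset_index()
    out.insert(1, "active_days", active.to_numpy())
    return out


def attach_participants(
    summaries: pd.DataFrame, participants: pd.DataFrame
) -> pd.DataFrame:
    """Join home zip and BMI onto participant summaries.

    *participants* has columns ``participant_id``, ``zip`` and ``bmi``
    (BMI may be missing). Zip codes are coerced to 5-character strings
    to preserve leading zeros.
    """
    p = participants.copy()
    p["zip"] = p["zip"].astype(str).str.zfill(5)
    merged = summaries.merge(
        p[["participant_id", "zip", "bmi"]], on="participant_id", how="left"
    )
    if merged["zip"].isna().any():
        missing = merged.loc[merged["zip"].isna(), "participant_id"].tolist()[:5]
        raise ValueError(f"participants missing from roster, e.g. {missing}")
    return merged


def filter_participants(summaries: pd.DataFrame, min_days: int = 10) -> pd.DataFrame:
    """Retain participants with at least *min_days* active days (inclusive)."""
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    kept = summaries[summaries["active_days"] >= min_days]
    log.info(
        "participant filter (>=%d active days): %d -> %d",
        min_days,
        len(summaries),
        len(kept),
    )
    return kept.reset_index(drop=True)


def zip_outcomes(summaries: pd.DataFrame, min_participants: int = 30) -> pd.DataFrame:
    """Aggregate participant summaries to zip-level outcome measures.

    Per zip: unweighted mean of participant rates per category, the
    participant count, and the overweight/obesity fraction — the share
    of BMI-reporting participants with BMI strictly greater than 25
    (NaN when no participant in the zip reports BMI). Zips with fewer
    than *min_participants* participants are dropped.
    """

    def _agg(group: pd.DataFrame) -> pd.Series:
        bmi = group["bmi"].dropna()
        return pd.Series(
            {
                "n_participants": len(group),
                "mean_fv": group["rate_fv"].mean(),
                "mean_fastfood": group["rate_fastfood"].mean(),
                "mean_soda": group["rate_soda"].mean(),
                "overweight_fraction": (
                    float((bmi > 25).sum()) / len(bmi) if len(bmi) else np.nan
                ),
            }
        )

    out = (
        summaries.groupby("zip", sort=True)[summaries.columns]
        .apply(_agg)
        .reset_index()
    )
    out["n_participants"] = out["n_participants"].astype(int)
    kept = out[out["n_participants"] >= min_participants].reset_index(drop=True)
    log.info(
        "zip filter (>=%d participants): %d -> %d zips",
        min_participants,
        len(out),
        len(kept),
    )
    n_missing = int(kept["overweight_fraction"].isna().sum())
    if n_missing:
        log.warning("%d zips have no BMI reporters; overweight_fraction missing", n_missing)
    return kept
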