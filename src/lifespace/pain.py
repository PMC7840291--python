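"""Day-level aggregation of momentary pain ratings.

Participants rate their current pain on an 11-point box scale (0 = no
pain ... 10 = worst possible pain) when prompted once in each of three
daily windows (morning 8-12, afternoon 12-16, evening 16-20).  The
analysis operates on days, so ratings are averaged across the answered
prompts of each day; days are also dichotomised into low (< 2) and high
(>= 2) mean pain for descriptive display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PAIN_MIN, PAIN_MAX = 0, 10
PAIN_GROUP_CUT = 2.0


def label_pain_group(mean_pain: float) -> str:
    """Dichotomise a day-mean pain score: low (< 2) or high (>= 2)."""
    if not np.isfinite(mean_pain) or not PAIN_MIN <= mean_pain <= PAIN_MAX:
        raise ValueError(f"mean pain {mean_pain!r} outside [0, 10]")
    return "high" if mean_pain >= PAIN_GROUP_CUT else "low"


def _window_from_hour(hour):
    return np.select(
        [(hour >= 8) & (hour < 12), (hour >= 12) & (hour < 16), (hour >= 16) & (hour < 20)],
        ["morning", "afternoon", "evening"],
        default="other",
    )


def aggregate_daily_pain(prompts: pd.DataFrame, min_prompts: int = 1) -> pd.DataFrame:
    """Collapse prompt-level ratings to one row per participant-day.

    Parameters
    ----------
    prompts
        Columns ``participant_id, timestamp, rating`` and optionally
        ``window``; unanswered prompts carry a missing rating.  At most one
        answered prompt per window per day is allowed.
    min_prompts
        Days with fewer answered prompts than this get a missing mean
        (default 1: any answered prompt yields a day mean).

    Returns
    -------
    DataFrame with ``participant_id, local_date, mean_pain, n_answered,
    group`` where ``group`` is low/high/missing.
    """
    df = prompts.copy()
    df["local_date"] = df["timestamp"].dt.date
    if "window" not in df.columns:
        df["window"] = _window_from_hour(df["timestamp"].dt.hour)
    answered = df[df["rating"].notna()]
    bad = answered[
        (answered["rating"] < PAIN_MIN)
        | (answered["rating"] > PAIN_MAX)
        | (answered["rating"] % 1 != 0)
    ]
    if len(bad):
        raise ValueError(
            f"ratings must be integers in [0, 10]; offending rows: "
            f"{bad.index.tolist()[:10]}"
        )
    dup = answered.groupby(["participant_id", "local_date", "window"]).size()
    dup = dup[dup > 1]
    if len(dup):
        raise ValueError(
            "multiple answered prompts in one window: "
            + "; ".join(f"{k[0]} {k[1]} {k[2]}" for k in dup.index[:10])
        )
    grouped = df.groupby(["participant_id", "local_date"], sort=True)
    out = grouped["rating"].agg(
        mean_pain="mean", n_answered="count"
    ).reset_index()
    out.loc[out["n_answered"] < min_prompts, "mean_pain"] = np.nan
    out["group"] = np.where(
        out["mean_pain"].isna(),
        "missing",
        np.where(out["mean_pain"] >= PAIN_GROUP_CUT, "high", "low"),
    )
    return out
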