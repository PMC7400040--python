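"""Respondent QC: exclusion rules and the attribution ledger.

Six rules are applied in a fixed order, and each excluded record is
attributed to the *first* rule it fails:

1. ``duplicate_source`` — all but the earliest submission per anonymized
   source identifier (no raw network addresses are stored);
2. ``too_fast`` — completion under 7 minutes (questions not actually read);
3. ``too_slow`` — completion over 1 hour (respondent not focused);
4. ``hard_to_understand`` — answered *no* to the ease-of-understanding
   question;
5. ``meal_gap`` — reported more than 16 hours since the last meal;
6. ``sleep_excess`` — reported more than 16 hours of sleep the previous
   night.

All boundaries keep the boundary value (exactly 7 minutes, exactly 16
hours are kept).  Records missing a metadata field are excluded under the
ledger-visible rule id ``invalid_metadata``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

RULE_IDS = (
    "invalid_metadata",
    "duplicate_source",
    "too_fast",
    "too_slow",
    "hard_to_understand",
    "meal_gap",
    "sleep_excess",
)

#: Metadata columns the rules require.
METADATA_COLUMNS = (
    "source_id",
    "completion_minutes",
    "easy_to_understand",
    "hours_since_meal",
    "hours_slept",
)

MIN_COMPLETION_MINUTES = 7.0
MAX_COMPLETION_MINUTES = 60.0
MAX_MEAL_GAP_HOURS = 16.0
MAX_SLEEP_HOURS = 16.0


@dataclass
class ExclusionLedger:
    """Accounting of how many records each rule removed."""

    total_in: int
    excluded: dict[str, int] = field(default_factory=dict)
    kept: int = 0

    @property
    def total_excluded(self) -> int:
        return sum(self.excluded.values())

    def percentages(self) -> dict[str, float]:
        if self.total_in == 0:
            return {r: 0.0 for r in self.excluded}
        return {
            r: 100.0 * n / self.total_in for r, n in self.excluded.items()
        }

    def to_dict(self) -> dict[str, Any]:
        return {
            "total_in": self.total_in,
            "kept": self.kept,
            "excluded": dict(self.excluded),
            "excluded_pct": {
                r: round(p, 2) for r, p in self.percentages().items()
            },
        }


def _truthy_ease(value: Any) -> bool | None:
    """Interpret the ease-of-understanding flag; None if unparseable."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("yes", "y", "true", "1"):
            return True
        if v in ("no", "n", "false", "0"):
            return False
    if isinstance(value, (int, float)) and not np.isnan(value):
        return bool(value)
    return None


def apply_exclusions(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the QC rules to a respondent table.

    Returns the kept records (original row order preserved) and a ledger
    whose counts attribute each exclusion to the first failing rule.
    Duplicate detection keeps the earliest ``timestamp`` per source id
    (row order breaks ties and stands in when no timestamp column exists).
    """
    df = records
    n = len(df)
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise KeyError(
            f"records lack required metadata columns: {missing_cols}"
        )

    meta_bad = pd.Series(False, index=df.index)
    numeric = {}
    for col in ("completion_minutes", "hours_since_meal", "hours_slept"):
        vals = pd.to_numeric(df[col], errors="coerce")
        numeric[col] = vals
        meta_bad |= vals.isna()
    ease = df["easy_to_understand"].map(_truthy_ease)
    meta_bad |= ease.isna()
    meta_bad |= df["source_id"].isna()
    reason[meta_bad] = "invalid_metadata"

    # duplicate_source: keep the earliest submission per source id
    order = df[["source_id"]].copy()
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        order["ts"] = ts.fillna(pd.Timestamp.max)  # unparseable: defer to row order
    else:
        order["ts"] = pd.Timestamp.max
    order["pos"] = np.arange(n)
    first_pos = (
        order.sort_values(["ts", "pos"])
        .groupby("source_id")["pos"]
        .transform("first")
        .reindex(order.index)
    )
    is_dup = (order["pos"] != first_pos) & ~meta_bad
    reason[is_dup & reason.isna()] = "duplicate_source"

    checks = [
        ("too_fast", numeric["completion_minutes"] < MIN_COMPLETION_MINUTES),
        ("too_slow", numeric["completion_minutes"] > MAX_COMPLETION_MINUTES),
        ("hard_to_understand", ease == False),  # noqa: E712
        ("meal_gap", numeric["hours_since_meal"] > MAX_MEAL_GAP_HOURS),
        ("sleep_excess", numeric["hours_slept"] > MAX_SLEEP_HOURS),
    ]
    for rule, mask in checks:
        mask = mask.fillna(False) & reason.isna()
        reason[mask] = rule

    kept = df[reason.isna()]
    ledger = ExclusionLedger(
        total_in=n,
        excluded={
            r: int((reason == r).sum())
            for r in RULE_IDS
            if (reason == r).any() or r != "invalid_metadata"
        },
        kept=len(kept),
    )
    return kept, ledger


def exclusion_reason(record: Mapping[str, Any]) -> str | None:
    """First failing rule for a single record (duplicates need context)."""
    df = pd.DataFrame([dict(record)])
    _, ledger = apply_exclusions(df)
    for rule, count in ledger.excluded.items():
        if count:
            return rule
    return None


class ResponseCleaner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the QC exclusion rules.

    ``transform`` returns the kept records; the attribution ledger from the
    most recent call is stored as ``ledger_``.
    """

    def fit(self, X=None, y=None) -> "ResponseCleaner":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept, self.ledger_ = apply_exclusions(X)
        return kept
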