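"""Six subcategory scores from the same weighted item values.

Each subcategory score is a weighted average of its constituent items'
rescaled-and-weighted values: items core to the subcategory carry weight
1.0, items secondary to it carry 0.5.  Like the overall score the average
is then normalized asymmetrically — positive averages onto [0, 100]
(anchored at the subcategory's attainable maximum), negative averages onto
the compressed window [-1, -50] (anchored at the attainable minimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .item_bank import ItemBank, validate_response_record
from . import scoring


@dataclass
class SubscoreResult:
    sub_id: str
    raw: float  # weighted average of the item values
    normalized: float  # on the -50..100 subscore scale


def subscore_anchors(bank: ItemBank) -> tuple[np.ndarray, np.ndarray]:
    """Attainable (min, max) raw weighted average per subcategory."""
    best, worst = scoring.item_extremes(bank)
    A = bank.subcategory_matrix
    denom = A.sum(axis=0)
    if np.any(denom == 0):
        empty = [
            s for s, d in zip(bank.subcategory_ids, denom) if d == 0
        ]
        raise ConfigError(f"subcategories with no items: {empty}")
    raw_max = (best @ A) / denom
    raw_min = (worst @ A) / denom
    return raw_min, raw_max


def _normalize_raw(
    raw: np.ndarray, raw_min: np.ndarray, raw_max: np.ndarray
) -> np.ndarray:
    if np.any(raw_max <= 0) or np.any(raw_min >= 0):
        raise ConfigError(
            "degenerate subscore anchors: require raw_min < 0 < raw_max"
        )
    positive = 100.0 * raw / raw_max
    negative = -1.0 - 49.0 * (raw / raw_min)
    # clip pure float overshoot at the theoretical bounds
    return np.clip(np.where(raw >= 0, positive, negative), -50.0, 100.0)


def subscore_frame(weighted: np.ndarray, bank: ItemBank) -> pd.DataFrame:
    """Normalized subscores for an (n, n_items) weighted-value array.

    NaN entries mark unanswered items (partial-scoring mode); anchors are
    then recomputed over the answered items of each record.
    """
    weighted = np.asarray(weighted, dtype=float)
    answered = ~np.isnan(weighted)
    A = bank.subcategory_matrix
    best, worst = scoring.item_extremes(bank)

    denom = answered @ A  # per-row sum of weights over answered items
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(answered, weighted, 0.0) @ A / denom
        raw_max = (np.where(answered, best, 0.0) @ A) / denom
        raw_min = (np.where(answered, worst, 0.0) @ A) / denom
        norm = _normalize_raw(np.nan_to_num(raw), raw_min, raw_max)
    norm = np.where(denom > 0, norm, np.nan)
    return pd.DataFrame(norm, columns=bank.subcategory_ids)


def compute_subscore(
    record: Mapping[str, Any], bank: ItemBank, sub_id: str
) -> SubscoreResult:
    """Compute one subcategory score for a single validated record."""
    if sub_id not in bank.subcategories:
        raise KeyError(f"unknown subcategory id {sub_id!r}")
    record = validate_response_record(record, bank)
    j = bank.subcategory_ids.index(sub_id)
    a = bank.subcategory_matrix[:, j]
    ratings = np.array([record[iid] for iid in bank.item_ids])
    weighted = scoring.weight_matrix(scoring.rescale_matrix(ratings, bank), bank)
    raw = float((weighted * a).sum() / a.sum())
    raw_min, raw_max = subscore_anchors(bank)
    normalized = float(
        _normalize_raw(
            np.array([raw]), raw_min[j : j + 1], raw_max[j : j + 1]
        )[0]
    )
    return SubscoreResult(sub_id=sub_id, raw=raw, normalized=normalized)


def compute_subscores(
    record: Mapping[str, Any], bank: ItemBank
) -> dict[str, SubscoreResult]:
    """All six subcategory scores for one record."""
    return {s: compute_subscore(record, bank, s) for s in bank.subcategory_ids}
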