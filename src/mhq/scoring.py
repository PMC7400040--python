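"""Overall MHQ computation: rescaling, negative weighting, normalization.

A raw 47-rating vector is transformed in two steps before aggregation:

1. *Threshold rescaling.*  Each item carries a threshold ``N`` (2-6) that
   splits the 1-9 rating scale into a healthy (positive) and clinical-risk
   (negative) side.  Problem items rescale as ``N - rating``; spectrum
   items as ``rating - N``.
2. *Nonlinear negative weighting.*  Nonnegative rescaled values pass
   through unchanged; negative values are amplified as
   ``-w * |x| ** gamma`` with a per-item severity weight ``w`` and exponent
   ``gamma``, so that a -7 on a grave item (say, suicidal thoughts) pulls
   the score down far more than a -7 on a mild one.

The 47 weighted values are summed into an intermediate score, then mapped
piecewise-linearly onto the asymmetric MHQ scale: positive sums stretch
over 0..+200 (anchored at the bank's attainable maximum), negative sums
compress into -1..-100 (anchored at the attainable minimum).  The smaller
negative window intentionally mitigates the distress of receiving a very
negative number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, RatingRangeError, ScoreRangeError
from .item_bank import (
    MAX_RATING,
    MIN_RATING,
    Item,
    ItemBank,
    load_item_bank,
    validate_response_record,
    validate_responses,
)

#: Score levels in ascending order with their closed integer bins.
LEVELS = ("clinical", "at_risk", "enduring", "managing", "succeeding", "thriving")
LEVEL_BINS: dict[str, tuple[int, int]] = {
    "clinical": (-100, -51),
    "at_risk": (-50, -1),
    "enduring": (0, 50),
    "managing": (51, 100),
    "succeeding": (101, 150),
    "thriving": (151, 200),
}


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------

def rescale_item(rating: int, item: Item) -> int:
    """Rescale a 1-9 rating onto the item's positive/negative scale.

    Problem items map to ``N - rating`` (1 is healthy); spectrum items to
    ``rating - N`` (9 is healthy).
    """
    if not MIN_RATING <= rating <= MAX_RATING:
        raise RatingRangeError(
            f"rating must be in [1, 9], got {rating!r}"
        )
    rating = int(rating)
    if item.format == "problem":
        return item.rescale_threshold - rating
    return rating - item.rescale_threshold


def weight_negative(rescaled: float, item: Item) -> float:
    """Apply the differential nonlinear weighting to a rescaled value.

    Nonnegative values pass through unchanged; negative values become
    ``-w * |x| ** gamma``, strictly decreasing in |x|.
    """
    if rescaled >= 0:
        return float(rescaled)
    return -item.severity_weight * abs(rescaled) ** item.severity_exponent


def rescale_matrix(ratings: np.ndarray, bank: ItemBank) -> np.ndarray:
    """Vectorized rescaling of an (n_respondents, n_items) rating array."""
    ratings = np.asarray(ratings)
    signed = np.where(bank.is_problem, bank.thresholds - ratings,
                      ratings - bank.thresholds)
    return signed


def weight_matrix(rescaled: np.ndarray, bank: ItemBank) -> np.ndarray:
    """Vectorized nonlinear negative weighting."""
    rescaled = np.asarray(rescaled, dtype=float)
    amplified = -bank.weights * np.abs(rescaled) ** bank.exponents
    return np.where(rescaled >= 0, rescaled, amplified)


def item_extremes(bank: ItemBank) -> tuple[np.ndarray, np.ndarray]:
    """Per-item (best, worst) weighted values attainable on the 1-9 scale."""
    best_ratings = np.where(bank.is_problem, MIN_RATING, MAX_RATING)
    worst_ratings = np.where(bank.is_problem, MAX_RATING, MIN_RATING)
    best = weight_matrix(rescale_matrix(best_ratings, bank), bank)
    worst = weight_matrix(rescale_matrix(worst_ratings, bank), bank)
    return best, worst


def bank_extremes(bank: ItemBank) -> tuple[float, float]:
    """Theoretical (S_min, S_max) of the intermediate score for a bank."""
    best, worst = item_extremes(bank)
    return float(worst.sum()), float(best.sum())


# ---------------------------------------------------------------------------
# aggregation and normalization
# ---------------------------------------------------------------------------

@dataclass
class IntermediateScore:
    """Sum of the 47 weighted item values with its attainable extremes."""

    value: float
    s_min: float  # theoretical minimum (< 0)
    s_max: float  # theoretical maximum (> 0)


@dataclass
class MHQResult:
    """Scored respondent: overall MHQ, level and the six subscores."""

    mhq: float
    level: str
    subscores: dict[str, float]
    intermediate: IntermediateScore | None = None
    rescaled: dict[str, int] = field(default_factory=dict)
    weighted: dict[str, float] = field(default_factory=dict)
    diagnostics: Any = None


def aggregate(record: Mapping[str, Any], bank: ItemBank) -> IntermediateScore:
    """Sum the weighted item values of a validated record.

    Missing ratings are a hard error — no silent imputation.
    """
    record = validate_response_record(record, bank)
    ratings = np.array([record[iid] for iid in bank.item_ids])
    value = float(weight_matrix(rescale_matrix(ratings, bank), bank).sum())
    s_min, s_max = bank_extremes(bank)
    return IntermediateScore(value=value, s_min=s_min, s_max=s_max)


def _normalize_values(
    values: np.ndarray, s_min: float | np.ndarray, s_max: float | np.ndarray
) -> np.ndarray:
    """Piecewise-linear map of intermediate sums onto the -100..+200 scale."""
    values = np.asarray(values, dtype=float)
    if np.any(np.asarray(s_max) <= 0) or np.any(np.asarray(s_min) >= 0):
        raise ConfigError(
            f"degenerate score extremes: require s_min < 0 < s_max, "
            f"got s_min={s_min}, s_max={s_max}"
        )
    positive = 200.0 * values / s_max
    negative = -1.0 - 99.0 * (values / s_min)
    # clip pure float overshoot at the theoretical bounds
    return np.clip(np.where(values >= 0, positive, negative), -100.0, 200.0)


def normalize_overall(score: IntermediateScore) -> float:
    """Map an intermediate score onto the MHQ scale.

    Nonnegative sums map linearly onto [0, 200] (max attains 200);
    negative sums map onto the compressed window [-100, -1) with the
    attainable minimum at -100 and the healthy edge at -1.
    """
    return float(
        _normalize_values(np.array([score.value]), score.s_min, score.s_max)[0]
    )


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (so -50.5 -> -51, 50.5 -> 51)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def assign_level(mhq: float) -> str:
    """Map an MHQ score to its interpretive level.

    The score is rounded half-away-from-zero to an integer and looked up in
    the six closed bins: clinical [-100, -51], at-risk [-50, -1],
    enduring [0, 50], managing [51, 100], succeeding [101, 150],
    thriving [151, 200].
    """
    if not -100 <= mhq <= 200:
        raise ScoreRangeError(f"MHQ score must be in [-100, 200], got {mhq}")
    rounded = int(_round_half_away(mhq))
    for level, (lo, hi) in LEVEL_BINS.items():
        if lo <= rounded <= hi:
            return level
    raise ScoreRangeError(f"rounded score {rounded} fell outside all bins")


def assign_levels(mhq: np.ndarray) -> np.ndarray:
    """Vectorized level assignment."""
    mhq = np.asarray(mhq, dtype=float)
    if mhq.size and (mhq.min() < -100 or mhq.max() > 200):
        raise ScoreRangeError("MHQ scores must be in [-100, 200]")
    rounded = _round_half_away(mhq)
    edges = np.array([-50, 0, 51, 101, 151])  # lower edges of bins 1..5
    idx = np.searchsorted(edges, rounded, side="right")
    return np.asarray(LEVELS)[idx]


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MHQScorer(BaseEstimator, TransformerMixin):
    """Transform respondent rating tables into MHQ scores.

    A stateless (configuration-driven) sklearn-style transformer: ``fit``
    resolves and validates the item bank and caches the attainable score
    extremes; ``transform`` maps a DataFrame with one column per item id
    (extra columns are preserved) to a score table with ``mhq``, ``level``
    and the six subscore columns.

    Parameters
    ----------
    bank :
        An :class:`~mhq.item_bank.ItemBank`, a path to a bank config, or
        None for the shipped default table.
    allow_partial :
        Off-spec convenience: when True, records may omit ratings and the
        normalization anchors are recomputed over answered items only.
        Default False (missing ratings are a hard error).
    include_items :
        When True, the transformed frame also carries per-item rescaled
        values as ``rescaled_<item_id>`` columns.

    Attributes
    ----------
    bank_ : ItemBank
        The resolved bank.
    s_min_, s_max_ : float
        Attainable extremes of the intermediate score.
    """

    def __init__(self, bank=None, allow_partial: bool = False,
                 include_items: bool = False):
        self.bank = bank
        self.allow_partial = allow_partial
        self.include_items = include_items

    def fit(self, X=None, y=None) -> "MHQScorer":
        bank = self.bank
        if not isinstance(bank, ItemBank):
            bank = load_item_bank(bank)
        self.bank_ = bank
        self.s_min_, self.s_max_ = bank_extremes(bank)
        self.n_features_in_ = len(bank)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "bank_"):
            self.fit()
        bank = self.bank_
        if self.allow_partial:
            ratings, answered = self._partial_ratings(X)
        else:
            X = validate_responses(X, bank)
            ratings = X[bank.item_ids].to_numpy(dtype=float)
            answered = np.ones_like(ratings, dtype=bool)

        rescaled = rescale_matrix(ratings, bank)
        weighted = weight_matrix(rescaled, bank)
        weighted = np.where(answered, weighted, 0.0)
        value = weighted.sum(axis=1)

        best, worst = item_extremes(bank)
        s_max = np.where(answered, best, 0.0).sum(axis=1)
        s_min = np.where(answered, worst, 0.0).sum(axis=1)
        mhq = _normalize_values(value, s_min, s_max)

        from . import subscores as _subscores  # local import: avoids cycle

        sub = _subscores.subscore_frame(
            np.where(answered, weighted, np.nan), bank
        )
        out = pd.DataFrame(index=X.index)
        if "respondent_id" in X.columns:
            out["respondent_id"] = X["respondent_id"]
        out["mhq"] = mhq
        out["level"] = assign_levels(mhq)
        for sub_id in bank.subcategory_ids:
            out[sub_id] = sub[sub_id].to_numpy()
        if self.include_items:
            for k, iid in enumerate(bank.item_ids):
                out[f"rescaled_{iid}"] = rescaled[:, k]
        return out

    def _partial_ratings(self, X: pd.DataFrame):
        bank = self.bank_
        present = [iid for iid in bank.item_ids if iid in X.columns]
        ratings = np.full((len(X), len(bank)), np.nan)
        for iid in present:
            ratings[:, bank.index(iid)] = X[iid].to_numpy(dtype=float)
        answered = ~np.isnan(ratings)
        if not answered.any(axis=1).all():
            raise RatingRangeError("a record answered no items at all")
        checked = np.where(answered, ratings, MIN_RATING)
        if (checked < MIN_RATING).any() or (checked > MAX_RATING).any():
            raise RatingRangeError("ratings must be in [1, 9]")
        ratings = np.where(answered, ratings, MIN_RATING)
        return ratings, answered

    def score_record(self, record: Mapping[str, Any]) -> MHQResult:
        """Score a single respondent record into an :class:`MHQResult`."""
        if not hasattr(self, "bank_"):
            self.fit()
        bank = self.bank_
        record = validate_response_record(record, bank)
        ratings = np.array([record[iid] for iid in bank.item_ids])
        rescaled = rescale_matrix(ratings, bank)
        weighted = weight_matrix(rescaled, bank)
        inter = IntermediateScore(
            value=float(weighted.sum()), s_min=self.s_min_, s_max=self.s_max_
        )
        mhq = normalize_overall(inter)

        from . import subscores as _subscores

        subs = {
            sub_id: _subscores.compute_subscore(record, bank, sub_id).normalized
            for sub_id in bank.subcategory_ids
        }
        return MHQResult(
            mhq=mhq,
            level=assign_level(mhq),
            subscores=subs,
            intermediate=inter,
            rescaled=dict(zip(bank.item_ids, (int(v) for v in rescaled))),
            weighted=dict(zip(bank.item_ids, (float(v) for v in weighted))),
        )


def score_responses(
    df: pd.DataFrame, bank: ItemBank | str | None = None, **kwargs
) -> pd.DataFrame:
    """Score a respondent table; thin wrapper over :class:`MHQScorer`."""
    return MHQScorer(bank=bank, **kwargs).fit().transform(df)


def score_record(
    record: Mapping[str, Any], bank: ItemBank | str | None = None
) -> MHQResult:
    """Score one respondent record; thin wrapper over :class:`MHQScorer`."""
    return MHQScorer(bank=bank).fit().score_record(record)
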