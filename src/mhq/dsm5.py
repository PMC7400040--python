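"""Rule-based DSM-5 symptom mapping for 10 disorders.

An item response on the severe side of its rescaling threshold (rescaled
value < 0: below N for spectrum items, above N for problem items) counts as
a DSM-level severe symptom.  Each disorder's rule lists criterion symptoms,
each backed by one or more items; a criterion is met when at least one of
its items is severe.  Per respondent the mapper reports, for each disorder:

* ``n`` — the number of met criterion symptoms,
* ``n / N_d`` as a percentage — the share of the disorder's symptoms shown,
* ``n / T`` as a percentage — the share of the respondent's severe symptoms
  attributable to the disorder (T = total met criteria across disorders),
* a positive/negative diagnostic indication from the criterion-derived
  algorithm: at least ``min_required`` symptoms and at least one symptom
  from every mandatory set.

Severity only: frequency and duration qualifiers of the DSM-5 are not
captured by a single-sitting questionnaire and are excluded.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError
from .item_bank import Item, ItemBank, load_item_bank, validate_responses
from . import scoring

DISORDERS = (
    "depression", "anxiety", "bipolar", "ptsd", "ocd",
    "schizophrenia", "eating_disorder", "addiction", "adhd", "asd",
)


@dataclass
class DisorderRule:
    """Criterion-derived diagnostic rule for one disorder."""

    disorder: str
    criteria: dict[str, list[str]]  # criterion id -> mapped item ids
    min_required: int
    required_any: list[list[str]]  # each set: >=1 member criterion must be met

    @property
    def total_symptoms(self) -> int:
        return len(self.criteria)

    def validate(self, bank: ItemBank | None = None) -> None:
        if not self.criteria:
            raise ConfigError(f"{self.disorder}: rule has no criteria")
        if not 1 <= self.min_required <= self.total_symptoms:
            raise ConfigError(
                f"{self.disorder}: min_required ({self.min_required}) must be "
                f"between 1 and the symptom count ({self.total_symptoms})"
            )
        for crit, items in self.criteria.items():
            if not items:
                raise ConfigError(
                    f"{self.disorder}/{crit}: criterion maps to no items"
                )
            if bank is not None:
                for iid in items:
                    if iid not in bank.item_ids:
                        raise ConfigError(
                            f"{self.disorder}/{crit}: unknown item id {iid!r}"
                        )
        for group in self.required_any:
            for crit in group:
                if crit not in self.criteria:
                    raise ConfigError(
                        f"{self.disorder}: required_any references unknown "
                        f"criterion {crit!r}"
                    )


def load_dsm5_rules(
    source: str | Path | Mapping[str, Any] | None = None,
    bank: ItemBank | None = None,
) -> dict[str, DisorderRule]:
    """Load the disorder rule table; None loads the shipped default.

    When a bank is supplied, every mapped item id is checked against it and
    each item's ``dsm_links`` field is populated with its
    (disorder, criterion) pairs.
    """
    if source is None:
        text = (resources.files("mhq") / "data" / "default_dsm5.yaml").read_text()
        config = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        config = copy.deepcopy(dict(source))
    else:
        with open(source) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "disorders" not in config:
        raise ConfigError("DSM-5 rule configuration must map 'disorders'")
    rules: dict[str, DisorderRule] = {}
    for disorder, entry in config["disorders"].items():
        for key in ("min_required", "criteria"):
            if key not in entry:
                raise ConfigError(f"{disorder}: missing required field {key!r}")
        rule = DisorderRule(
            disorder=disorder,
            criteria={c: list(ids) for c, ids in entry["criteria"].items()},
            min_required=int(entry["min_required"]),
            required_any=[list(g) for g in entry.get("required_any") or []],
        )
        rule.validate(bank)
        rules[disorder] = rule
    if bank is not None:
        link_bank(bank, rules)
    return rules


def link_bank(bank: ItemBank, rules: Mapping[str, DisorderRule]) -> None:
    """Populate each item's ``dsm_links`` with its (disorder, criterion) pairs."""
    links: dict[str, list[tuple[str, str]]] = {iid: [] for iid in bank.item_ids}
    for rule in rules.values():
        for crit, items in rule.criteria.items():
            for iid in items:
                if iid not in links:
                    raise ConfigError(
                        f"{rule.disorder}/{crit}: unknown item id {iid!r}"
                    )
                links[iid].append((rule.disorder, crit))
    for item in bank.items:
        item.dsm_links = links[item.item_id]


# ---------------------------------------------------------------------------
# severity and profiles
# ---------------------------------------------------------------------------

def is_severe(rating: int, item: Item) -> bool:
    """Whether a rating meets the DSM severity criterion for its item.

    Spectrum: rating below N; problem: rating above N.  Identical to the
    rescaled value being negative.
    """
    if item.format == "problem":
        return rating > item.rescale_threshold
    return rating < item.rescale_threshold


def round_half_up(x: float) -> int:
    """Integer percent rounding with halves up (6/11 -> 55, 4/6 -> 67)."""
    return int(np.floor(x + 0.5))


@dataclass
class DiagnosticProfile:
    """Per-disorder severe-symptom counts, percentages and indications."""

    rows: dict[str, dict[str, Any]]  # disorder -> n, total, pcts, indication
    total_severe: int  # T: met criterion symptoms across all disorders

    def to_table(self) -> pd.DataFrame:
        """Wide per-disorder table (one row per disorder)."""
        return pd.DataFrame(
            [
                {
                    "disorder": d,
                    "severe_symptoms": r["n"],
                    "total_symptoms": r["total"],
                    "disorder_pct": r["disorder_pct"],
                    "individual_pct": r["individual_pct"],
                    "indication": r["indication"],
                }
                for d, r in self.rows.items()
            ]
        )


def _criterion_matrix(
    severe: np.ndarray, bank: ItemBank, rule: DisorderRule
) -> np.ndarray:
    """(n_respondents, n_criteria) bool array of met criteria."""
    cols = []
    for items in rule.criteria.values():
        idx = [bank.index(iid) for iid in items]
        cols.append(severe[:, idx].any(axis=1))
    return np.column_stack(cols)


def profiles_frame(
    df: pd.DataFrame,
    bank: ItemBank,
    rules: Mapping[str, DisorderRule] | None = None,
) -> pd.DataFrame:
    """Vectorized diagnostic profiles for a respondent table.

    Returns one row per respondent with, per disorder, ``<d>_n``,
    ``<d>_pct``, ``<d>_individual_pct`` and ``<d>_indication`` columns,
    plus ``total_severe`` (T) and ``any_positive``.
    """
    if rules is None:
        rules = load_dsm5_rules(bank=bank)
    df = validate_responses(df, bank)
    ratings = df[bank.item_ids].to_numpy()
    severe = scoring.rescale_matrix(ratings, bank) < 0

    counts: dict[str, np.ndarray] = {}
    indications: dict[str, np.ndarray] = {}
    for disorder, rule in rules.items():
        met = _criterion_matrix(severe, bank, rule)
        n = met.sum(axis=1)
        ok = n >= rule.min_required
        crit_ids = list(rule.criteria)
        for group in rule.required_any:
            gidx = [crit_ids.index(c) for c in group]
            ok &= met[:, gidx].any(axis=1)
        counts[disorder] = n
        indications[disorder] = ok

    total = sum(counts.values())
    out = pd.DataFrame(index=df.index)
    if "respondent_id" in df.columns:
        out["respondent_id"] = df["respondent_id"]
    half_up = lambda x: np.floor(x + 0.5).astype(int)  # noqa: E731
    for disorder, rule in rules.items():
        n = counts[disorder]
        out[f"{disorder}_n"] = n
        out[f"{disorder}_pct"] = half_up(100.0 * n / rule.total_symptoms)
        with np.errstate(invalid="ignore", divide="ignore"):
            ipct = np.where(total > 0, 100.0 * n / np.maximum(total, 1), 0.0)
        out[f"{disorder}_individual_pct"] = half_up(ipct)
        out[f"{disorder}_indication"] = np.where(
            indications[disorder], "positive", "negative"
        )
    out["total_severe"] = total
    out["any_positive"] = np.column_stack(
        [indications[d] for d in rules]
    ).any(axis=1)
    return out


def build_profile(
    record: Mapping[str, Any],
    bank: ItemBank,
    rules: Mapping[str, DisorderRule] | None = None,
) -> DiagnosticProfile:
    """Diagnostic profile for a single validated record."""
    frame = profiles_frame(pd.DataFrame([dict(record)]), bank, rules)
    if rules is None:
        rules = load_dsm5_rules(bank=bank)
    row = frame.iloc[0]
    rows = {
        d: {
            "n": int(row[f"{d}_n"]),
            "total": rules[d].total_symptoms,
            "disorder_pct": int(row[f"{d}_pct"]),
            "individual_pct": int(row[f"{d}_individual_pct"]),
            "indication": row[f"{d}_indication"],
        }
        for d in rules
    }
    return DiagnosticProfile(rows=rows, total_severe=int(row["total_severe"]))


def cohort_concordance(
    scores: pd.DataFrame | Sequence, profiles: pd.DataFrame | Sequence
) -> pd.DataFrame:
    """Per-level concordance between MHQ levels and diagnostic indications.

    For each score level: the fraction of respondents with at least one
    positive indication and their mean severe-symptom count.
    """
    if not isinstance(scores, pd.DataFrame):
        scores = pd.DataFrame({"level": [r.level for r in scores]})
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(
            {
                "any_positive": [
                    any(r["indication"] == "positive" for r in p.rows.values())
                    for p in profiles
                ],
                "total_severe": [p.total_severe for p in profiles],
            }
        )
    if len(scores) != len(profiles):
        raise ValueError(
            f"scores ({len(scores)}) and profiles ({len(profiles)}) differ in length"
        )
    if scores.empty:
        return pd.DataFrame(
            columns=["level", "n", "frac_positive", "mean_severe_symptoms"]
        )
    joined = pd.DataFrame(
        {
            "level": scores["level"].to_numpy(),
            "any_positive": profiles["any_positive"].to_numpy(),
            "total_severe": profiles["total_severe"].to_numpy(),
        }
    )
    rows = []
    for level in scoring.LEVELS:
        grp = joined[joined["level"] == level]
        if grp.empty:
            continue
        rows.append(
            {
                "level": level,
                "n": len(grp),
                "frac_positive": grp["any_positive"].mean(),
                "mean_severe_symptoms": grp["total_severe"].mean(),
            }
        )
    return pd.DataFrame(rows)


class DSMMapper(BaseEstimator, TransformerMixin):
    """Transform respondent rating tables into diagnostic profiles.

    Parameters
    ----------
    bank :
        Item bank (object, path or None for the default).
    rules :
        Disorder rules (mapping, path or None for the default).
    """

    def __init__(self, bank=None, rules=None):
        self.bank = bank
        self.rules = rules

    def fit(self, X=None, y=None) -> "DSMMapper":
        bank = self.bank
        if not isinstance(bank, ItemBank):
            bank = load_item_bank(bank)
        rules = self.rules
        is_rule_map = isinstance(rules, Mapping) and all(
            isinstance(r, DisorderRule) for r in rules.values()
        )
        if not is_rule_map:
            rules = load_dsm5_rules(rules, bank=bank)
        self.bank_ = bank
        self.rules_ = rules
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "bank_"):
            self.fit()
        return profiles_frame(X, self.bank_, self.rules_)
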