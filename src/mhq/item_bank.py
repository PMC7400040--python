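"""The 47-item instrument definition and response-schema validation.

The Mental Health Quotient (MHQ) instrument consists of 47 items rated on a
1-9 scale.  Items come in two formats: *spectrum* items run from severe
impairment (1) to life asset (9), while *problem* items run from "never a
problem" (1) to "constant severe impact" (9).  Every scoring parameter —
the per-item rescaling threshold ``N``, the severity weight and exponent of
the nonlinear negative weighting, and the subcategory assignment weights —
lives in a single versioned configuration file so nothing is hard-coded in
the engine.  :func:`load_item_bank` with no arguments loads the shipped
default table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    IncompleteRecordError,
    IneligibleError,
    RatingRangeError,
    SchemaError,
)

SPECTRUM = "spectrum"
PROBLEM = "problem"

#: Canonical subcategory ids, fixed by the instrument design.
SUBCATEGORY_IDS = (
    "core_cognition",
    "complex_cognition",
    "mood_outlook",
    "drive_motivation",
    "social_self",
    "mind_body",
)

#: Eligible age brackets (respondents under 18 are not eligible).
AGE_BRACKETS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65+")

GENDERS = ("female", "male", "nonbinary/third", "prefer-not-to-say")

MIN_RATING, MAX_RATING = 1, 9


@dataclass
class Item:
    """One of the 47 question definitions with its scoring parameters."""

    item_id: str
    label: str
    description: str
    format: str  # SPECTRUM or PROBLEM
    rescale_threshold: int  # N: splits the 1-9 scale, 2 <= N <= 6
    severity_weight: float  # w > 0: negative-side amplification factor
    severity_exponent: float  # gamma >= 1: negative-side power
    subcategory_weights: dict[str, float] = field(default_factory=dict)
    dsm_links: list[tuple[str, str]] = field(default_factory=list)
    rationale: str = ""

    def validate(self) -> None:
        if self.format not in (SPECTRUM, PROBLEM):
            raise ConfigError(
                f"item {self.item_id!r}: format must be 'spectrum' or 'problem', "
                f"got {self.format!r}"
            )
        if self.rescale_threshold not in (2, 3, 4, 5, 6):
            raise ConfigError(
                f"item {self.item_id!r}: rescale threshold N must be an integer "
                f"between 2 and 6, got {self.rescale_threshold!r}"
            )
        if not self.severity_weight > 0:
            raise ConfigError(
                f"item {self.item_id!r}: severity weight must be positive, "
                f"got {self.severity_weight!r}"
            )
        if not self.severity_exponent >= 1:
            raise ConfigError(
                f"item {self.item_id!r}: severity exponent must be >= 1, "
                f"got {self.severity_exponent!r}"
            )
        if not 1 <= len(self.subcategory_weights) <= 3:
            raise ConfigError(
                f"item {self.item_id!r}: must be assigned to between 1 and 3 "
                f"subcategories, got {len(self.subcategory_weights)}"
            )
        for sub, w in self.subcategory_weights.items():
            if w not in (1.0, 0.5):
                raise ConfigError(
                    f"item {self.item_id!r}: subcategory weight for {sub!r} must "
                    f"be 1.0 (core) or 0.5 (secondary), got {w!r}"
                )


@dataclass
class Subcategory:
    """One of the six mental-health domains."""

    sub_id: str
    name: str
    description: str


class ItemBank:
    """Ordered, validated collection of the instrument's items.

    Parameters
    ----------
    items :
        Item definitions, in presentation-independent canonical order.
    subcategories :
        The six domain definitions keyed by id.
    version :
        Configuration version string carried through round-trips.
    strict :
        When True (default), enforce the full-instrument invariants
        (47 items: 27 spectrum, 20 problem; 6 subcategories each assigned
        10-24 items).  Reduced banks for testing pass ``strict=False``;
        per-item invariants are always enforced.
    """

    def __init__(
        self,
        items: Iterable[Item],
        subcategories: Mapping[str, Subcategory],
        version: str = "unversioned",
        strict: bool = True,
    ):
        self.items: list[Item] = list(items)
        self.subcategories: dict[str, Subcategory] = dict(subcategories)
        self.version = version
        self.strict = strict
        self._validate()
        self._build_arrays()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for item in self.items:
            item.validate()
            if item.item_id in seen:
                raise ConfigError(f"duplicate item id {item.item_id!r}")
            seen.add(item.item_id)
            for sub in item.subcategory_weights:
                if sub not in self.subcategories:
                    raise ConfigError(
                        f"item {item.item_id!r} references unknown subcategory {sub!r}"
                    )
        if not self.strict:
            return
        n = len(self.items)
        if n != 47:
            raise ConfigError(f"item bank must contain exactly 47 items, got {n}")
        n_spec = sum(1 for i in self.items if i.format == SPECTRUM)
        n_prob = n - n_spec
        if n_spec != 27 or n_prob != 20:
            raise ConfigError(
                f"item bank must contain 27 spectrum and 20 problem items, "
                f"got {n_spec} spectrum and {n_prob} problem"
            )
        if set(self.subcategories) != set(SUBCATEGORY_IDS):
            raise ConfigError(
                f"item bank must define exactly the 6 subcategories "
                f"{SUBCATEGORY_IDS}, got {sorted(self.subcategories)}"
            )
        for sub_id in SUBCATEGORY_IDS:
            size = sum(
                1 for i in self.items if sub_id in i.subcategory_weights
            )
            if not 10 <= size <= 24:
                raise ConfigError(
                    f"subcategory {sub_id!r} must comprise 10 to 24 items, "
                    f"got {size}"
                )

    def _build_arrays(self) -> None:
        """Precompute vectorized parameter arrays in item order."""
        self.item_ids: list[str] = [i.item_id for i in self.items]
        self._index = {iid: k for k, iid in enumerate(self.item_ids)}
        self.thresholds = np.array(
            [i.rescale_threshold for i in self.items], dtype=np.int64
        )
        self.weights = np.array([i.severity_weight for i in self.items])
        self.exponents = np.array([i.severity_exponent for i in self.items])
        self.is_problem = np.array(
            [i.format == PROBLEM for i in self.items], dtype=bool
        )
        # subcategory weight matrix: items x subcategories, 0 where unassigned
        self.subcategory_ids: list[str] = [
            s for s in SUBCATEGORY_IDS if s in self.subcategories
        ] + [s for s in self.subcategories if s not in SUBCATEGORY_IDS]
        A = np.zeros((len(self.items), len(self.subcategory_ids)))
        for k, item in enumerate(self.items):
            for j, sub in enumerate(self.subcategory_ids):
                A[k, j] = item.subcategory_weights.get(sub, 0.0)
        self.subcategory_matrix = A

    # -- access ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: str) -> Item:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def index(self, item_id: str) -> int:
        return self._index[item_id]

    @property
    def spectrum_items(self) -> list[Item]:
        return [i for i in self.items if i.format == SPECTRUM]

    @property
    def problem_items(self) -> list[Item]:
        return [i for i in self.items if i.format == PROBLEM]

    def items_in_subcategory(self, sub_id: str) -> list[Item]:
        if sub_id not in self.subcategories:
            raise KeyError(f"unknown subcategory id {sub_id!r}")
        return [i for i in self.items if sub_id in i.subcategory_weights]

    # -- round-trip ------------------------------------------------------

    def to_config(self) -> dict[str, Any]:
        """Serialize back to the configuration schema (round-trip stable)."""
        return {
            "version": self.version,
            "subcategories": {
                s.sub_id: {"name": s.name, "description": s.description}
                for s in self.subcategories.values()
            },
            "items": [
                {
                    "id": i.item_id,
                    "label": i.label,
                    "description": i.description,
                    "format": i.format,
                    "threshold": i.rescale_threshold,
                    "weight": i.severity_weight,
                    "exponent": i.severity_exponent,
                    "subcategories": dict(i.subcategory_weights),
                    **({"rationale": i.rationale} if i.rationale else {}),
                }
                for i in self.items
            ],
        }


def _default_config_text(name: str) -> str:
    return (resources.files("mhq") / "data" / name).read_text()


def _parse_items(config: Mapping[str, Any]) -> ItemBank:
    if "items" not in config:
        raise ConfigError("configuration has no 'items' section")
    subs = {}
    for sub_id, entry in (config.get("subcategories") or {}).items():
        if not isinstance(entry, Mapping) or "description" not in entry:
            raise ConfigError(f"subcategory {sub_id!r}: missing description")
        subs[sub_id] = Subcategory(
            sub_id=sub_id,
            name=entry.get("name", sub_id),
            description=entry["description"],
        )
    items = []
    for entry in config["items"]:
        if not isinstance(entry, Mapping) or "id" not in entry:
            raise ConfigError(f"malformed item entry: {entry!r}")
        iid = entry["id"]
        for key in ("format", "threshold", "weight", "exponent", "subcategories"):
            if key not in entry:
                raise ConfigError(f"item {iid!r}: missing required field {key!r}")
        threshold = entry["threshold"]
        if not isinstance(threshold, int) or isinstance(threshold, bool):
            raise ConfigError(
                f"item {iid!r}: threshold must be an integer, got {threshold!r}"
            )
        items.append(
            Item(
                item_id=iid,
                label=entry.get("label", iid),
                description=entry.get("description", ""),
                format=entry["format"],
                rescale_threshold=threshold,
                severity_weight=float(entry["weight"]),
                severity_exponent=float(entry["exponent"]),
                subcategory_weights={
                    k: float(v) for k, v in entry["subcategories"].items()
                },
                rationale=entry.get("rationale", ""),
            )
        )
    return ItemBank(
        items,
        subs,
        version=str(config.get("version", "unversioned")),
        strict=bool(config.get("strict", True)),
    )


def load_item_bank(
    source: str | Path | Mapping[str, Any] | None = None,
) -> ItemBank:
    """Load and validate an item bank from configuration.

    Parameters
    ----------
    source :
        Path to a YAML/JSON file, an already-parsed mapping, or None for
        the shipped default parameter table.

    Returns
    -------
    ItemBank
        Validated bank; loading is deterministic and preserves item order.
    """
    if source is None:
        config = yaml.safe_load(_default_config_text("default_bank.yaml"))
    elif isinstance(source, Mapping):
        config = copy.deepcopy(dict(source))
    else:
        with open(source) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigError("item bank configuration must be a mapping")
    return _parse_items(config)


def dump_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank back to YAML in the loadable schema."""
    with open(path, "w") as fh:
        yaml.safe_dump(bank.to_config(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# response-schema validation
# ---------------------------------------------------------------------------

def _check_demographics(record: Mapping[str, Any]) -> None:
    age = record.get("age_bracket")
    if age is not None and age not in AGE_BRACKETS:
        # a bare number below 18 is an eligibility failure, anything else a
        # schema failure
        try:
            if float(age) < 18:
                raise IneligibleError(
                    f"respondents younger than 18 are not eligible (got age {age!r})"
                )
        except (TypeError, ValueError):
            pass
        raise SchemaError(
            f"age_bracket must be one of {AGE_BRACKETS}, got {age!r}"
        )
    gender = record.get("gender")
    if gender is not None and gender not in GENDERS:
        raise SchemaError(f"gender must be one of {GENDERS}, got {gender!r}")


def validate_response_record(
    record: Mapping[str, Any], bank: ItemBank
) -> dict[str, Any]:
    """Validate a single respondent record against the bank's schema.

    Ratings must be integers in [1, 9] for every item in the bank;
    demographic enums are checked when present.  Non-item fields are passed
    through untouched.

    Raises
    ------
    IncompleteRecordError
        If any item rating is missing.
    RatingRangeError
        If a rating is outside [1, 9] or not integral.
    IneligibleError, SchemaError
        On demographic violations.
    """
    missing = [
        iid
        for iid in bank.item_ids
        if record.get(iid) is None
        or (isinstance(record.get(iid), float) and np.isnan(record[iid]))
    ]
    if missing:
        raise IncompleteRecordError(missing)
    out = dict(record)
    for iid in bank.item_ids:
        value = record[iid]
        try:
            rating = int(value)
        except (TypeError, ValueError):
            raise RatingRangeError(
                f"item {iid!r}: rating must be an integer, got {value!r}"
            ) from None
        if rating != value and not float(value).is_integer():
            raise RatingRangeError(
                f"item {iid!r}: rating must be an integer, got {value!r}"
            )
        if not MIN_RATING <= rating <= MAX_RATING:
            raise RatingRangeError(
                f"item {iid!r}: rating must be in [1, 9], got {rating}"
            )
        out[iid] = rating
    _check_demographics(record)
    return out


def validate_responses(df: pd.DataFrame, bank: ItemBank) -> pd.DataFrame:
    """Validate a respondent table (one row per respondent) against the bank.

    Returns a copy with item columns coerced to integers.  Raises on the
    first violating record, naming the row label.
    """
    missing_cols = [iid for iid in bank.item_ids if iid not in df.columns]
    if missing_cols:
        raise IncompleteRecordError(missing_cols)
    ratings = df[bank.item_ids]
    if ratings.isna().any().any():
        bad = ratings.isna().any(axis=1)
        row = df.index[bad][0]
        raise IncompleteRecordError(
            ratings.columns[ratings.loc[row].isna()].tolist()
        )
    values = ratings.to_numpy()
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise RatingRangeError("ratings must be integers")
    values = values.astype(np.int64)
    if values.min() < MIN_RATING or values.max() > MAX_RATING:
        rows, cols = np.where((values < MIN_RATING) | (values > MAX_RATING))
        iid = bank.item_ids[cols[0]]
        raise RatingRangeError(
            f"item {iid!r}: rating must be in [1, 9], got "
            f"{values[rows[0], cols[0]]} (row {df.index[rows[0]]!r})"
        )
    out = df.copy()
    out[bank.item_ids] = values
    if "age_bracket" in out.columns or "gender" in out.columns:
        for _, rec in out.iterrows():
            _check_demographics(rec)
    return out
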