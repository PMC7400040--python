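"""Per-respondent reports and cohort-level summaries.

The individual report is plain Markdown (with a JSON sidecar available via
:func:`result_to_dict`): overall score, level, a level-keyed recommendation
and the six subscores with their domain descriptions.  The recommendation
texts ship as clearly marked placeholders — the production instrument's
prose is not published — keyed by level so deployments can substitute their
own.  Cohort summaries aggregate scores into width-10 histogram bins, level
proportions, cumulative curves by gender and age bracket, and subscore
level breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cleaning import ExclusionLedger
from .errors import MHQError
from .item_bank import AGE_BRACKETS, ItemBank
from .scoring import LEVELS, MHQResult, _round_half_away

#: Level bins on the -50..100 subscore scale (half the overall bins).
SUBSCORE_LEVEL_BINS: dict[str, tuple[int, int]] = {
    "clinical": (-50, -26),
    "at_risk": (-25, -1),
    "enduring": (0, 25),
    "managing": (26, 50),
    "succeeding": (51, 75),
    "thriving": (76, 100),
}

#: Placeholder recommendation texts keyed by level.  [PLACEHOLDER] blocks
#: are meant to be replaced by deployment-specific guidance.
DEFAULT_TEMPLATES: dict[str, str] = {
    "clinical": (
        "[PLACEHOLDER] Your responses place you in the clinical range. "
        "Please consider seeking support from a qualified mental health "
        "professional as soon as you can."
    ),
    "at_risk": (
        "[PLACEHOLDER] Your responses suggest you may be at risk. "
        "Consider talking to someone you trust or a professional."
    ),
    "enduring": "[PLACEHOLDER] You are getting by; targeted habits could help.",
    "managing": "[PLACEHOLDER] You are managing well in most areas.",
    "succeeding": "[PLACEHOLDER] You are doing well across most domains.",
    "thriving": "[PLACEHOLDER] You are thriving; keep doing what works.",
}


def assign_subscore_level(subscore: float) -> str:
    """Map a -50..100 subscore to its interpretive level."""
    if not -50 <= subscore <= 100:
        raise MHQError(f"subscore must be in [-50, 100], got {subscore}")
    rounded = int(_round_half_away(subscore))
    for level, (lo, hi) in SUBSCORE_LEVEL_BINS.items():
        if lo <= rounded <= hi:
            return level
    raise MHQError(f"rounded subscore {rounded} fell outside all bins")


def result_to_dict(result: MHQResult) -> dict[str, Any]:
    """JSON-ready dictionary form of a scored respondent."""
    return {
        "mhq": round(result.mhq, 1),
        "level": result.level,
        "subscores": {k: round(v, 1) for k, v in result.subscores.items()},
        "subscore_levels": {
            k: assign_subscore_level(v) for k, v in result.subscores.items()
        },
    }


def render_individual_report(
    result: MHQResult,
    bank: ItemBank,
    templates: Mapping[str, str] | None = None,
) -> str:
    """Render a respondent's Markdown report; deterministic.

    Raises KeyError naming the level or subcategory whose template or
    description is missing.
    """
    templates = DEFAULT_TEMPLATES if templates is None else templates
    if result.level not in templates:
        raise KeyError(f"no recommendation template for level {result.level!r}")
    lines = [
        "# Your MHQ report",
        "",
        f"**Overall MHQ score: {result.mhq:.1f}** (scale -100 to +200)",
        f"**Level: {result.level.replace('_', '-')}**",
        "",
        templates[result.level],
        "",
        "## Subcategory scores (scale -50 to +100)",
        "",
    ]
    for sub_id, value in result.subscores.items():
        if sub_id not in bank.subcategories:
            raise KeyError(f"no description for subcategory {sub_id!r}")
        sub = bank.subcategories[sub_id]
        level = assign_subscore_level(value)
        lines += [
            f"### {sub.name}: {value:.1f} ({level.replace('_', '-')})",
            "",
            sub.description,
            "",
        ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

#: Grid for cumulative score curves.
HIST_EDGES = np.arange(-100, 201, 10)

#: Lower bounds of the width-10 integer score windows: -100..-91 ... -10..-1,
#: then 0..10, 11..20, ..., 191..200.  Windows never straddle a level edge,
#: so each level is an exact union of windows.
WINDOW_LOWERS = np.concatenate(
    [np.arange(-100, 0, 10), [0], np.arange(11, 200, 10)]
)


def _window_lower(rounded: np.ndarray) -> np.ndarray:
    """Map rounded integer scores to their window's lower bound."""
    rounded = np.asarray(rounded, dtype=int)
    neg = (np.floor_divide(rounded, 10)) * 10
    pos = np.where(rounded <= 10, 0, ((rounded - 1) // 10) * 10 + 1)
    return np.where(rounded < 0, neg, pos)


@dataclass
class CohortSummary:
    """Aggregate view of a scored cohort."""

    n: int
    histogram: pd.Series  # counts per width-10 MHQ bin
    level_proportions: dict[str, float]
    negative_proportion: float
    mean_mhq: float
    cumulative_by_gender: pd.DataFrame | None = None
    cumulative_by_age: pd.DataFrame | None = None
    subscore_levels: pd.DataFrame | None = None  # subcategory x level props
    ledger: ExclusionLedger | None = None

    @property
    def empty(self) -> bool:
        return self.n == 0


def _cumulative(values: np.ndarray) -> np.ndarray:
    """Cumulative fraction of scores at or below each histogram edge."""
    return np.array([(values <= e).mean() for e in HIST_EDGES])


def summarize_cohort(
    results: pd.DataFrame,
    records: pd.DataFrame | None = None,
    ledger: ExclusionLedger | None = None,
    bank: ItemBank | None = None,
) -> CohortSummary:
    """Summarize a scored cohort.

    Parameters
    ----------
    results :
        Score table from the scorer (``mhq``, ``level``, subscore columns).
    records :
        The matching respondent table (for gender/age breakdowns).
    """
    if len(results) == 0:
        return CohortSummary(
            n=0,
            histogram=pd.Series(0, index=WINDOW_LOWERS),
            level_proportions={lv: 0.0 for lv in LEVELS},
            negative_proportion=0.0,
            mean_mhq=float("nan"),
            ledger=ledger,
        )
    mhq = results["mhq"].to_numpy(dtype=float)
    lowers = _window_lower(_round_half_away(mhq))
    histogram = pd.Series(
        [(lowers == lo).sum() for lo in WINDOW_LOWERS],
        index=WINDOW_LOWERS,
        name="count",
    )
    level_props = {
        lv: float((results["level"] == lv).mean()) for lv in LEVELS
    }

    cum_gender = cum_age = None
    if records is not None:
        if len(records) != len(results):
            raise ValueError("records and results differ in length")
        if "gender" in records.columns:
            cum_gender = pd.DataFrame(
                {
                    g: _cumulative(mhq[records["gender"].to_numpy() == g])
                    for g in pd.unique(records["gender"])
                    if (records["gender"] == g).any()
                },
                index=HIST_EDGES,
            )
        if "age_bracket" in records.columns:
            cum_age = pd.DataFrame(
                {
                    a: _cumulative(mhq[records["age_bracket"].to_numpy() == a])
                    for a in AGE_BRACKETS
                    if (records["age_bracket"] == a).any()
                },
                index=HIST_EDGES,
            )

    sub_levels = None
    sub_cols = [c for c in results.columns if c in (
        "core_cognition", "complex_cognition", "mood_outlook",
        "drive_motivation", "social_self", "mind_body",
    )]
    if sub_cols:
        rows = {}
        for col in sub_cols:
            levels = [assign_subscore_level(v) for v in results[col]]
            s = pd.Series(levels)
            rows[col] = {
                lv: float((s == lv).mean()) for lv in LEVELS
            }
        sub_levels = pd.DataFrame(rows).T[list(LEVELS)]

    return CohortSummary(
        n=len(results),
        histogram=histogram,
        level_proportions=level_props,
        negative_proportion=float((mhq < 0).mean()),
        mean_mhq=float(mhq.mean()),
        cumulative_by_gender=cum_gender,
        cumulative_by_age=cum_age,
        subscore_levels=sub_levels,
        ledger=ledger,
    )


def summary_to_dict(summary: CohortSummary) -> dict[str, Any]:
    out: dict[str, Any] = {
        "n": summary.n,
        "mean_mhq": None if np.isnan(summary.mean_mhq) else round(summary.mean_mhq, 2),
        "negative_proportion": round(summary.negative_proportion, 4),
        "level_proportions": {
            k: round(v, 4) for k, v in summary.level_proportions.items()
        },
        "histogram": {int(k): int(v) for k, v in summary.histogram.items()},
    }
    if summary.ledger is not None:
        out["exclusions"] = summary.ledger.to_dict()
    if summary.subscore_levels is not None:
        out["subscore_levels"] = {
            sub: {k: round(v, 4) for k, v in row.items()}
            for sub, row in summary.subscore_levels.iterrows()
        }
    return out


def plot_summary(summary: CohortSummary, path: str) -> None:
    """Write a PNG of the score distribution (negative bins shaded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    edges = summary.histogram.index.to_numpy()
    colors = ["0.6" if e < 0 else "0.1" for e in edges]
    ax.bar(edges, summary.histogram.to_numpy(), width=9, align="edge",
           color=colors)
    ax.set_xlabel("MHQ score")
    ax.set_ylabel("respondents")
    ax.set_title(f"MHQ distribution (n={summary.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
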