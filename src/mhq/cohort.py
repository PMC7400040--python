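"""Synthetic respondent cohorts with the structure the instrument assumes.

Real respondent data for this instrument are not publicly deposited, so the
package ships a generative model that reproduces the *statistical shape* a
general-population sample is described as having: a healthy majority, a
smaller at-risk band and a clinical tail with disorder-clustered severe
symptoms, a gender gap concentrated on mood and mind-body items, an age
gradient of increasing well-being, and QC-violating records at configurable
rates.

The response model is a monotone ordinal discretization of a latent
well-being factor ``z``: per item, a latent value ``u = z(+shifts) +
noise`` maps to the 1-9 scale as ``round(N + gain*u)`` for spectrum items
and ``round(N - gain*u)`` for problem items (clipped to [1, 9]).  Centering
at each item's own threshold ``N`` makes ``u < 0`` line up with the severe
side of the scale.  With ``noise_sd = 0`` the map from ``z`` to every
rating — and hence to the MHQ — is deterministic and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .item_bank import AGE_BRACKETS, GENDERS, ItemBank, load_item_bank
from . import dsm5 as _dsm5

#: Default demographic mixes and group fractions; these defaults emulate the
#: published general-population validation sample.
DEFAULT_GENDER_MIX = {
    "female": 0.6114,
    "male": 0.3658,
    "nonbinary/third": 0.0108,
    "prefer-not-to-say": 0.0120,
}
DEFAULT_AGE_MIX = {
    "18-24": 0.1471,
    "25-34": 0.2667,
    "35-44": 0.2000,
    "45-54": 0.1700,
    "55-64": 0.1460,
    "65+": 0.0702,
}
DEFAULT_QC_RATES = {
    "duplicate_source": 0.0285,
    "too_fast": 0.0627,
    "too_slow": 0.0239,
    "hard_to_understand": 0.0204,
    "meal_gap": 0.0198,
    "sleep_excess": 0.0051,
}
DEFAULT_DISORDER_WEIGHTS = {
    "depression": 0.30,
    "anxiety": 0.25,
    "bipolar": 0.08,
    "ptsd": 0.10,
    "ocd": 0.07,
    "schizophrenia": 0.03,
    "eating_disorder": 0.05,
    "addiction": 0.05,
    "adhd": 0.05,
    "asd": 0.02,
}


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    The latent well-being factor z is drawn per group (healthy / at-risk /
    clinical), shifted by a per-bracket age gradient and, on mood- and
    mind-body-linked items only, by a gender effect for the designated
    group.  Clinical respondents additionally concentrate severity on the
    items of one sampled disorder.
    """

    n: int = 2000
    seed: int = 0
    clinical_fraction: float = 0.0246
    at_risk_fraction: float = 0.1309
    gender_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_MIX)
    )
    age_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_MIX)
    )
    gender_effect: float = -0.35  # z shift on mood/mind-body items
    affected_gender: str = "female"
    age_gradient: float = 0.12  # z shift per bracket above the center
    qc_violation_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QC_RATES)
    )
    disorder_cluster_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISORDER_WEIGHTS)
    )
    # latent-model shape
    healthy_mean: float = 1.10
    healthy_sd: float = 0.55
    at_risk_mean: float = -0.25
    at_risk_sd: float = 0.25
    clinical_mean: float = -1.30
    clinical_sd: float = 0.40
    noise_sd: float = 0.50  # per-item rating noise
    gain: float = 2.50  # rating-scale steps per latent unit
    cluster_boost: float = 1.20  # extra severity on the sampled disorder's items

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"cohort size n must be >= 1, got {self.n}")
        for name in ("clinical_fraction", "at_risk_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.clinical_fraction + self.at_risk_fraction > 1:
            raise ConfigError("clinical + at-risk fractions exceed 1")
        for name, mix, allowed in (
            ("gender_mix", self.gender_mix, GENDERS),
            ("age_mix", self.age_mix, AGE_BRACKETS),
        ):
            bad = set(mix) - set(allowed)
            if bad:
                raise ConfigError(f"{name} has unknown categories: {sorted(bad)}")
            if any(p < 0 for p in mix.values()) or sum(mix.values()) <= 0:
                raise ConfigError(f"{name} probabilities must be nonnegative")
        for rule, p in self.qc_violation_rates.items():
            if not 0 <= p <= 1:
                raise ConfigError(
                    f"qc_violation_rates[{rule!r}] must be in [0, 1], got {p}"
                )
        if self.noise_sd < 0 or self.gain <= 0:
            raise ConfigError("noise_sd must be >= 0 and gain > 0")


def _sample_categorical(rng, categories, probs, n):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return rng.choice(categories, size=n, p=p)


def generate_cohort(
    spec: CohortSpec,
    bank: ItemBank | None = None,
    rules: Mapping[str, _dsm5.DisorderRule] | None = None,
) -> pd.DataFrame:
    """Generate a respondent table; deterministic given ``spec.seed``.

    The output carries the scorer's CSV schema (one column per item id,
    demographics, momentary/experiential fields, QC metadata) plus the
    generator's ground truth as ``latent_z`` and ``cohort_group`` columns.
    """
    spec.validate()
    if bank is None:
        bank = load_item_bank()
    if rules is None:
        rules = _dsm5.load_dsm5_rules(bank=bank)
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # -- group structure and latent well-being ---------------------------
    groups = _sample_categorical(
        rng,
        ["healthy", "at_risk", "clinical"],
        [
            1 - spec.at_risk_fraction - spec.clinical_fraction,
            spec.at_risk_fraction,
            spec.clinical_fraction,
        ],
        n,
    )
    means = {"healthy": spec.healthy_mean, "at_risk": spec.at_risk_mean,
             "clinical": spec.clinical_mean}
    sds = {"healthy": spec.healthy_sd, "at_risk": spec.at_risk_sd,
           "clinical": spec.clinical_sd}
    z = np.array(
        [rng.normal(means[g], sds[g]) for g in groups]
    )

    gender = _sample_categorical(
        rng, list(spec.gender_mix), list(spec.gender_mix.values()), n
    )
    age = _sample_categorical(
        rng, list(spec.age_mix), list(spec.age_mix.values()), n
    )
    age_idx = np.array([AGE_BRACKETS.index(a) for a in age])
    z = z + spec.age_gradient * (age_idx - (len(AGE_BRACKETS) - 1) / 2)

    # -- per-item latent values -----------------------------------------
    n_items = len(bank)
    mood_linked = np.array(
        [
            bool(
                set(i.subcategory_weights) & {"mood_outlook", "mind_body"}
            )
            for i in bank.items
        ]
    )
    u = z[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, n_items)) \
        if spec.noise_sd > 0 else np.tile(z[:, None], (1, n_items))
    u = u + spec.gender_effect * (
        (gender == spec.affected_gender)[:, None] & mood_linked[None, :]
    )

    # clinical respondents: concentrate severity on one sampled disorder
    if spec.disorder_cluster_weights and (groups == "clinical").any():
        disorders = list(spec.disorder_cluster_weights)
        dprobs = list(spec.disorder_cluster_weights.values())
        cluster = np.full(n, "", dtype=object)
        clin = np.flatnonzero(groups == "clinical")
        cluster[clin] = _sample_categorical(rng, disorders, dprobs, len(clin))
        item_of = {d: set() for d in disorders}
        for d in disorders:
            if d in rules:
                for items in rules[d].criteria.values():
                    item_of[d].update(items)
        for i in clin:
            idx = [bank.index(iid) for iid in item_of[cluster[i]]]
            u[i, idx] -= spec.cluster_boost
    else:
        cluster = np.full(n, "", dtype=object)

    # -- ordinal discretization onto the 1-9 scale -----------------------
    steps = np.rint(spec.gain * u)
    ratings = np.where(
        bank.is_problem[None, :],
        bank.thresholds[None, :] - steps,
        bank.thresholds[None, :] + steps,
    )
    ratings = np.clip(ratings, 1, 9).astype(np.int64)

    # -- metadata, momentary and experiential fields ---------------------
    completion = np.clip(rng.normal(14.0, 3.0, n), 8.0, 30.0)
    meal_gap = np.clip(rng.exponential(4.0, n), 0.0, 16.0)
    sleep = np.clip(rng.normal(7.4, 1.3, n), 3.0, 16.0)
    ease = np.full(n, "yes", dtype=object)
    source = np.array([f"src-{k:06d}" for k in range(n)], dtype=object)
    timestamps = pd.date_range("2019-07-01", periods=n, freq="17min")

    rates = dict(spec.qc_violation_rates)
    for rule, p in rates.items():
        hit = rng.random(n) < p
        if rule == "duplicate_source":
            for i in np.flatnonzero(hit):
                if i > 0:
                    source[i] = source[rng.integers(0, i)]
        elif rule == "too_fast":
            completion[hit] = rng.uniform(2.0, 6.9, hit.sum())
        elif rule == "too_slow":
            completion[hit] = rng.uniform(61.0, 23 * 60.0, hit.sum())
        elif rule == "hard_to_understand":
            ease[hit] = "no"
        elif rule == "meal_gap":
            meal_gap[hit] = rng.uniform(17.0, 52.0, hit.sum())
        elif rule == "sleep_excess":
            sleep[hit] = rng.uniform(17.0, 85.0, hit.sum())
        else:
            raise ConfigError(f"unknown QC rule id {rule!r}")

    out = pd.DataFrame(ratings, columns=bank.item_ids)
    out.insert(0, "respondent_id", [f"r{k:06d}" for k in range(n)])
    out["gender"] = gender
    out["age_bracket"] = age
    out["country"] = rng.choice(
        ["US", "GB", "CA", "IN", "other"], size=n, p=[0.48, 0.09, 0.06, 0.05, 0.32]
    )
    out["hours_slept"] = np.round(sleep, 1)
    out["hours_since_meal"] = np.round(meal_gap, 1)
    out["alertness"] = rng.integers(4, 10, n)
    out["mood"] = np.clip(np.rint(5 + 1.5 * z), 1, 9).astype(int)
    out["life_satisfaction"] = np.clip(np.rint(5 + 1.5 * z), 1, 9).astype(int)
    out["reported_trauma"] = rng.random(n) < 0.25
    out["diagnosed_disorder"] = (groups == "clinical") & (rng.random(n) < 0.5)
    out["treatment_seeking"] = (groups != "healthy") & (rng.random(n) < 0.3)
    out["completion_minutes"] = np.round(completion, 1)
    out["easy_to_understand"] = ease
    out["source_id"] = source
    out["timestamp"] = timestamps.astype(str)
    out["latent_z"] = z
    out["cohort_group"] = groups
    out["cluster_disorder"] = cluster
    return out


# ---------------------------------------------------------------------------
# structure recovery
# ---------------------------------------------------------------------------

def goodman_kruskal_gamma(x, y) -> float:
    """Goodman-Kruskal gamma: (C - D) / (C + D) over all pairs.

    The natural rank-correlation statistic under heavy ties: a monotone
    nondecreasing map produces no discordant pairs, giving gamma = 1
    exactly even where distinct x collapse onto the same y.
    O(n^2); intended for cohorts up to a few thousand.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    s = dx * dy
    concordant = np.count_nonzero(s > 0)
    discordant = np.count_nonzero(s < 0)
    if concordant + discordant == 0:
        return float("nan")
    return (concordant - discordant) / (concordant + discordant)


def recover_structure(
    scored: pd.DataFrame, affected_gender: str = "female"
) -> dict[str, float]:
    """Check that injected generative structure is visible in MHQ scores.

    Parameters
    ----------
    scored :
        Cohort with ``mhq`` plus the generator's ``latent_z``, ``gender``
        and ``age_bracket`` columns.

    Returns
    -------
    dict with:
      ``rank_correlation`` — Goodman-Kruskal gamma between latent z and mhq
      (1.0 for a noiseless monotone discretization); ``spearman`` — the
      tie-adjusted Spearman rho for reference; ``gender_negative_gap`` —
      negative-score proportion of the designated gender minus the rest;
      ``age_slope`` — OLS slope of mhq on age-bracket index;
      ``age_trend_sign`` — its sign.
    """
    for col in ("mhq", "latent_z", "gender", "age_bracket"):
        if col not in scored.columns:
            raise KeyError(f"scored cohort lacks column {col!r}")
    z = scored["latent_z"].to_numpy(dtype=float)
    mhq = scored["mhq"].to_numpy(dtype=float)
    gamma = goodman_kruskal_gamma(z, mhq)
    rho = float(stats.spearmanr(z, mhq).statistic) if len(z) > 1 else float("nan")

    affected = scored["gender"].to_numpy() == affected_gender
    neg = mhq < 0
    if affected.any() and (~affected).any():
        gap = float(neg[affected].mean() - neg[~affected].mean())
    else:
        gap = float("nan")

    age_idx = scored["age_bracket"].map(
        {b: i for i, b in enumerate(AGE_BRACKETS)}
    ).to_numpy(dtype=float)
    if np.ptp(age_idx) > 0:
        slope = float(np.polyfit(age_idx, mhq, 1)[0])
    else:
        slope = float("nan")
    return {
        "rank_correlation": float(gamma),
        "spearman": rho,
        "gender_negative_gap": gap,
        "age_slope": slope,
        "age_trend_sign": float(np.sign(slope)) if np.isfinite(slope) else float("nan"),
    }
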