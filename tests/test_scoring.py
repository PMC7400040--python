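"""Rescaling, negative weighting, normalization and level assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mhq.errors import ConfigError, IncompleteRecordError, RatingRangeError, ScoreRangeError
from mhq.item_bank import Item
from mhq.scoring import (
    LEVEL_BINS,
    LEVELS,
    IntermediateScore,
    MHQScorer,
    _normalize_values,
    aggregate,
    assign_level,
    assign_levels,
    bank_extremes,
    normalize_overall,
    rescale_item,
    score_record,
    score_responses,
    weight_negative,
)

from conftest import make_best_record, make_worst_record, random_ratings_frame


def make_item(fmt, threshold, weight=1.0, exponent=1.5):
    return Item(
        item_id=f"{fmt}_{threshold}", label="", description="", format=fmt,
        rescale_threshold=threshold, severity_weight=weight,
        severity_exponent=exponent, subcategory_weights={"core_cognition": 1.0},
    )


class TestRescaling:
    @pytest.mark.parametrize(
        "fmt,threshold,rating,expected",
        [
            ("problem", 2, 1, 1),
            ("problem", 2, 9, -7),
            ("problem", 4, 1, 3),
            ("problem", 4, 9, -5),
            ("spectrum", 3, 1, -2),
            ("spectrum", 3, 9, 6),
            ("spectrum", 3, 3, 0),  # rating = N is the scale split point
        ],
    )
    def test_worked_examples(self, fmt, threshold, rating, expected):
        assert rescale_item(rating, make_item(fmt, threshold)) == expected

    @pytest.mark.parametrize("rating", [0, 10])
    def test_rating_out_of_scale_rejected(self, rating):
        with pytest.raises(RatingRangeError):
            rescale_item(rating, make_item("problem", 2))

    def test_rescaled_range_by_format(self):
        for threshold in range(2, 7):
            for rating in range(1, 10):
                p = rescale_item(rating, make_item("problem", threshold))
                s = rescale_item(rating, make_item("spectrum", threshold))
                assert threshold - 9 <= p <= threshold - 1
                assert 1 - threshold <= s <= 9 - threshold


class TestNegativeWeighting:
    @pytest.mark.parametrize("value", [0, 3, 5])
    def test_nonnegative_pass_through(self, value):
        assert weight_negative(value, make_item("problem", 4, 2.0)) == value

    def test_power_law_amplification(self):
        item = make_item("problem", 2, weight=2.0, exponent=1.5)
        assert weight_negative(-4, item) == pytest.approx(-2.0 * 4**1.5)

    def test_graver_item_weighted_more_negatively(self):
        # same -7, but the grave (tier A) item amplifies more than the mild one
        grave = make_item("problem", 2, weight=3.0)
        mild = make_item("problem", 2, weight=1.0)
        assert weight_negative(-7, grave) < weight_negative(-7, mild)

    def test_strictly_decreasing_in_magnitude(self):
        item = make_item("spectrum", 4, weight=1.5, exponent=1.5)
        values = [weight_negative(-x, item) for x in range(1, 8)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestAggregation:
    def test_extreme_records_attain_extremes(self, bank, best_record, worst_record):
        s_min, s_max = bank_extremes(bank)
        assert aggregate(best_record, bank).value == pytest.approx(s_max)
        assert aggregate(worst_record, bank).value == pytest.approx(s_min)

    def test_single_step_from_best_changes_sum_by_one(self, bank, best_record):
        s_min, s_max = bank_extremes(bank)
        record = dict(best_record)
        record[bank.problem_items[0].item_id] = 2  # one step inside positive side
        assert aggregate(record, bank).value == pytest.approx(s_max - 1)

    def test_incomplete_record_is_hard_error(self, bank, best_record):
        record = dict(best_record)
        del record["memory"]
        with pytest.raises(IncompleteRecordError):
            aggregate(record, bank)


class TestNormalization:
    def score(self, value, s_min=-500.0, s_max=200.0):
        return normalize_overall(IntermediateScore(value, s_min, s_max))

    def test_endpoints(self):
        assert self.score(200.0) == pytest.approx(200.0)
        assert self.score(-500.0) == pytest.approx(-100.0)
        assert self.score(0.0) == pytest.approx(0.0)

    def test_positive_side_linear(self):
        assert self.score(100.0) == pytest.approx(100.0)

    def test_negative_midpoint(self):
        # halfway to the attainable minimum: -1 - 99/2 = -50.5
        assert self.score(-250.0) == pytest.approx(-50.5)

    def test_negative_side_approaches_minus_one(self):
        assert self.score(-1e-9) == pytest.approx(-1.0)

    def test_monotone_nondecreasing(self):
        values = np.linspace(-500, 200, 2001)
        mhq = _normalize_values(values, -500.0, 200.0)
        assert np.all(np.diff(mhq) >= 0)

    def test_degenerate_extremes_rejected(self):
        with pytest.raises(ConfigError):
            normalize_overall(IntermediateScore(0.0, -500.0, -1.0))
        with pytest.raises(ConfigError):
            normalize_overall(IntermediateScore(0.0, 1.0, 200.0))


class TestLevelAssignment:
    @pytest.mark.parametrize(
        "mhq,expected",
        [
            (151, "thriving"), (200, "thriving"),
            (101, "succeeding"), (150, "succeeding"),
            (51, "managing"), (100, "managing"),
            (0, "enduring"), (50, "enduring"),
            (-1, "at_risk"), (-50, "at_risk"),
            (-51, "clinical"), (-100, "clinical"),
            (-50.4, "at_risk"), (-50.6, "clinical"),
        ],
    )
    def test_bin_assignment(self, mhq, expected):
        assert assign_level(mhq) == expected

    def test_half_away_from_zero_at_edges(self):
        assert assign_level(-50.5) == "clinical"
        assert assign_level(50.5) == "managing"
        assert assign_level(-0.5) == "at_risk"

    def test_total_partition_over_edge_grid(self):
        """Every bin edge +/- a sub-unit grid maps to exactly one level."""
        edges = sorted({b for lo_hi in LEVEL_BINS.values() for b in lo_hi})
        grid = []
        for e in edges:
            grid.extend(
                e + d for d in (-0.5, -0.4, -0.1, 0.0, 0.1, 0.4, 0.5)
            )
        grid = [g for g in grid if -100 <= g <= 200]
        for g in grid:
            level = assign_level(g)  # raises if unassigned
            lo, hi = LEVEL_BINS[level]
            rounded = float(np.copysign(np.floor(abs(g) + 0.5), g))
            assert lo <= rounded <= hi
        # vectorized path agrees with the scalar path
        assert list(assign_levels(np.array(grid))) == [
            assign_level(g) for g in grid
        ]

    def test_integer_bins_cover_range_exactly_once(self):
        covered = sorted(
            x for lo, hi in LEVEL_BINS.values() for x in range(lo, hi + 1)
        )
        assert covered == list(range(-100, 201))

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoreRangeError):
            assign_level(201)
        with pytest.raises(ScoreRangeError):
            assign_level(-101)


class TestPipelineProperties:
    def test_bounds_and_extremes_over_random_records(self, bank):
        df = random_ratings_frame(bank, 2000, seed=11)
        scores = score_responses(df, bank)
        assert scores["mhq"].between(-100, 200).all()
        # extremes attained only by the all-best / all-worst vectors
        assert (scores["mhq"] > -100).all() and (scores["mhq"] < 200).all()

    def test_sign_equivalence(self, bank):
        df = random_ratings_frame(bank, 500, seed=3)
        scorer = MHQScorer(bank=bank).fit()
        scores = scorer.transform(df)
        from mhq.scoring import rescale_matrix, weight_matrix

        inter = weight_matrix(
            rescale_matrix(df[bank.item_ids].to_numpy(), bank), bank
        ).sum(axis=1)
        neg = scores["mhq"].to_numpy() < 0
        assert np.array_equal(neg, inter < 0)
        assert np.array_equal(
            neg, scores["level"].isin(["clinical", "at_risk"]).to_numpy()
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.data(),
    )
    def test_single_step_improvement_never_decreases_mhq(self, bank, data):
        ratings = data.draw(
            st.lists(st.integers(1, 9), min_size=47, max_size=47)
        )
        k = data.draw(st.integers(0, 46))
        record = dict(zip(bank.item_ids, ratings))
        item = bank.items[k]
        before = score_record(record, bank).mhq
        if item.format == "problem" and record[item.item_id] > 1:
            record[item.item_id] -= 1
        elif item.format == "spectrum" and record[item.item_id] < 9:
            record[item.item_id] += 1
        else:
            return
        after = score_record(record, bank).mhq
        assert after >= before

    def test_compression_doubles_mass_left_of_zero(self):
        """Uniform intermediate scores near 0 put ~2x the mass in the bin
        left of 0: the negative scale is half as long as the positive."""
        s = 300.0  # symmetric attainable extremes
        rng = np.random.default_rng(5)
        values = rng.uniform(-0.1 * s, 0.1 * s, 200_000)
        mhq = _normalize_values(values, -s, s)
        left = ((mhq >= -10) & (mhq < 0)).mean()
        right = ((mhq >= 0) & (mhq < 10)).mean()
        assert 1.6 < left / right < 2.1

    def test_three_item_oracle_over_all_vectors(self, toy3_bank):
        """Pipeline score equals a brute-force direct computation on the
        reduced bank over all 9**3 rating vectors."""

        def brute(r1, r2, r3):
            # independent direct evaluation of the published formulas
            spec = [("spectrum", 3, 2.0, 1.5), ("spectrum", 5, 1.0, 1.5),
                    ("problem", 2, 3.0, 1.5)]
            total = s_max = s_min = 0.0
            for rating, (fmt, N, w, g) in zip((r1, r2, r3), spec):
                x = (N - rating) if fmt == "problem" else (rating - N)
                total += x if x >= 0 else -w * abs(x) ** g
                best = (N - 1) if fmt == "problem" else (9 - N)
                worst = (N - 9) if fmt == "problem" else (1 - N)
                s_max += best
                s_min += -w * abs(worst) ** g
            if total >= 0:
                return 200.0 * total / s_max
            return -1.0 - 99.0 * total / s_min

        grid = [
            (r1, r2, r3)
            for r1 in range(1, 10)
            for r2 in range(1, 10)
            for r3 in range(1, 10)
        ]
        df = pd.DataFrame(grid, columns=toy3_bank.item_ids)
        scores = score_responses(df, toy3_bank)
        expected = np.array([brute(*g) for g in grid])
        np.testing.assert_allclose(scores["mhq"].to_numpy(), expected, atol=1e-9)


class TestScorerEstimator:
    def test_fit_exposes_extremes(self, bank):
        scorer = MHQScorer(bank=bank).fit()
        s_min, s_max = bank_extremes(bank)
        assert scorer.s_min_ == pytest.approx(s_min)
        assert scorer.s_max_ == pytest.approx(s_max)

    def test_get_set_params_round_trip(self, bank):
        scorer = MHQScorer(bank=bank, allow_partial=True)
        params = scorer.get_params()
        clone = MHQScorer().set_params(**params)
        assert clone.allow_partial is True

    def test_transform_preserves_respondent_id(self, bank):
        df = random_ratings_frame(bank, 5, seed=0)
        df.insert(0, "respondent_id", [f"r{i}" for i in range(5)])
        scores = MHQScorer(bank=bank).fit().transform(df)
        assert list(scores["respondent_id"]) == list(df["respondent_id"])
        assert {"mhq", "level"} <= set(scores.columns)

    def test_allow_partial_scores_answered_subset(self, bank, best_record):
        df = pd.DataFrame([best_record]).drop(
            columns=[bank.spectrum_items[0].item_id]
        )
        scores = MHQScorer(bank=bank, allow_partial=True).fit().transform(df)
        # all answered items at their best still attains the maximum
        assert scores["mhq"].iloc[0] == pytest.approx(200.0)

    def test_pipeline_compatible(self, bank):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("score", MHQScorer(bank=bank))])
        df = random_ratings_frame(bank, 10, seed=1)
        out = pipe.fit_transform(df)
        assert len(out) == 10
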