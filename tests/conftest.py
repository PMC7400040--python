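import numpy as np
import pandas as pd
import pytest

from mhq.item_bank import Item, ItemBank, Subcategory, load_item_bank
from mhq.dsm5 import load_dsm5_rules


@pytest.fixture(scope="session")
def bank():
    return load_item_bank()


@pytest.fixture(scope="session")
def rules(bank):
    return load_dsm5_rules(bank=bank)


def make_best_record(bank):
    """Most favorable rating on every item (spectrum 9, problem 1)."""
    return {
        i.item_id: (1 if i.format == "problem" else 9) for i in bank.items
    }


def make_worst_record(bank):
    """Least favorable rating on every item (spectrum 1, problem 9)."""
    return {
        i.item_id: (9 if i.format == "problem" else 1) for i in bank.items
    }


@pytest.fixture
def best_record(bank):
    return make_best_record(bank)


@pytest.fixture
def worst_record(bank):
    return make_worst_record(bank)


def random_ratings_frame(bank, n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.integers(1, 10, size=(n, len(bank))), columns=bank.item_ids
    )


@pytest.fixture
def toy3_bank():
    """Reduced 3-item bank (2 spectrum + 1 problem, 2 subcategories)."""
    subs = {
        "alpha": Subcategory("alpha", "Alpha", "toy cognition-like domain"),
        "beta": Subcategory("beta", "Beta", "toy mood-like domain"),
    }
    items = [
        Item("s_grave", "Grave spectrum", "", "spectrum", 3, 2.0, 1.5,
             {"alpha": 1.0}),
        Item("s_mild", "Mild spectrum", "", "spectrum", 5, 1.0, 1.5,
             {"alpha": 0.5, "beta": 1.0}),
        Item("p_grave", "Grave problem", "", "problem", 2, 3.0, 1.5,
             {"beta": 1.0}),
    ]
    return ItemBank(items, subs, version="toy3", strict=False)


def make_metadata(n, start="2020-01-01"):
    """Clean QC metadata for n records."""
    return pd.DataFrame(
        {
            "source_id": [f"s{i}" for i in range(n)],
            "completion_minutes": [14.0] * n,
            "easy_to_understand": ["yes"] * n,
            "hours_since_meal": [3.0] * n,
            "hours_slept": [8.0] * n,
            "timestamp": pd.date_range(start, periods=n, freq="h").astype(str),
        }
    )
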