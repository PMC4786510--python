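"""Shared fixtures: the bundled worked-example data and random datasets."""

from itertools import combinations

import numpy as np
import pytest

from ontoapriori import data
from ontoapriori.ontology import load_ontology
from ontoapriori.transactions import (
    Item,
    Itemset,
    ItemizedDataset,
    ValidationError,
    itemize,
    load_transactions,
    positive_value_filter,
    support,
)

# Canonical item ids of the 5-feature worked example.
CANCER = "Gastric cancer=yes"
SURGERY = "History of stomach surgery=yes"
MILK = "Milk consumption=yes"
SMOKING = "Smoking=yes"
FAMILY = "Family history of gastric cancer=yes"


@pytest.fixture(scope="session")
def example_table():
    return load_transactions(data.example_table_path())


@pytest.fixture(scope="session")
def example_ds(example_table):
    """Positive-value itemization of the 10-record worked-example table."""
    return itemize(example_table, positive_value_filter())


@pytest.fixture(scope="session")
def example_onto():
    return load_ontology(data.example_ontology_path())


@pytest.fixture(scope="session")
def risk_onto():
    return load_ontology(data.risk_factor_ontology_path())


def random_dataset(rng: np.random.Generator, max_items: int = 12,
                   max_rows: int = 64) -> ItemizedDataset:
    """Random boolean dataset with one binary item per feature."""
    m = int(rng.integers(3, max_items + 1))
    n = int(rng.integers(4, max_rows + 1))
    density = rng.uniform(0.2, 0.8)
    occurrence = rng.random((n, m)) < density
    items = tuple(Item(f"f{j:02d}", "yes") for j in range(m))
    return ItemizedDataset(items, occurrence)


def brute_force_frequent(ds: ItemizedDataset, min_support: float):
    """Independent oracle: enumerate every valid itemset and keep the
    frequent ones.  O(2^items); for tiny catalogues only."""
    out = {}
    threshold = min_support * ds.n - 1e-9
    for r in range(1, len(ds.item_ids) + 1):
        for combo in combinations(ds.item_ids, r):
            try:
                s = Itemset(combo)
            except ValidationError:
                continue  # two values of one feature can never co-occur
            count = int(ds.contains_rows(s).sum())
            if count >= threshold:
                out[s] = count / ds.n
    return out
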