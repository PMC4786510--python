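"""Categorical transaction tables and their binary itemized form.

A *transaction* is one patient record: a mapping from feature names to
categorical values.  Mining operates on *items* — ``feature=value`` pairs —
so a table is first itemized into a boolean occurrence matrix (one column
per observed item, one row per record).  Support of an itemset is the
fraction of rows containing every one of its items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FeatureSchema",
    "TransactionTable",
    "Item",
    "Itemset",
    "ItemizedDataset",
    "load_transactions",
    "itemize",
    "positive_value_filter",
    "support",
]


class ValidationError(ValueError):
    """Raised when a table, schema, or itemset violates its contract."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered catalogue of features and their allowed categorical values."""

    features: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate feature names: {dupes}")
        for name, values in self.features:
            if not values:
                raise ValidationError(f"feature {name!r} has no allowed values")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "FeatureSchema":
        return cls(tuple((name, frozenset(vals)) for name, vals in mapping.items()))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)

    def allowed_values(self, feature: str) -> frozenset[str]:
        for name, values in self.features:
            if name == feature:
                return values
        raise KeyError(feature)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class TransactionTable:
    """Validated list of records; record ids are 1-based row numbers."""

    records: tuple[Mapping[str, str], ...]
    schema: FeatureSchema

    def __post_init__(self) -> None:
        known = set(self.schema.feature_names)
        for i, record in enumerate(self.records, start=1):
            for feature, value in record.items():
                if feature not in known:
                    raise ValidationError(
                        f"record {i}: unknown feature {feature!r}"
                    )
                if value not in self.schema.allowed_values(feature):
                    raise ValidationError(
                        f"record {i}: value {value!r} not allowed for "
                        f"feature {feature!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Item:
    """A single feature=value pair; ``id`` is its canonical text form."""

    feature: str
    value: str

    @property
    def id(self) -> str:
        return f"{self.feature}={self.value}"

    @staticmethod
    def from_id(item_id: str) -> "Item":
        feature, sep, value = item_id.partition("=")
        if not sep:
            raise ValidationError(f"malformed item id {item_id!r}")
        return Item(feature, value)


def item_feature(item_id: str) -> str:
    """Feature name encoded in a canonical item id."""
    feature, sep, _ = item_id.partition("=")
    if not sep:
        raise ValidationError(f"malformed item id {item_id!r}")
    return feature


@dataclass(frozen=True, order=True)
class Itemset:
    """Sorted, duplicate-free set of item ids with at most one item per feature."""

    items: tuple[str, ...]

    def __init__(self, items: Iterable[str]) -> None:
        ordered = tuple(sorted(set(items)))
        features = [item_feature(i) for i in ordered]
        if len(features) != len(set(features)):
            raise ValidationError(
                f"itemset {ordered} holds two items of the same feature"
            )
        object.__setattr__(self, "items", ordered)

    @property
    def k(self) -> int:
        return len(self.items)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(item_feature(i) for i in self.items)

    def union(self, other: "Itemset | Iterable[str]") -> "Itemset":
        other_items = other.items if isinstance(other, Itemset) else tuple(other)
        return Itemset(self.items + other_items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.items

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __str__(self) -> str:
        return "{" + ", ".join(self.items) + "}"


@dataclass
class ItemizedDataset:
    """Boolean transaction-by-item occurrence matrix plus item catalogue."""

    items: tuple[Item, ...]
    occurrence: np.ndarray  # shape (n, len(items)), dtype bool
    n: int = field(init=False)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=bool)
        if self.occurrence.ndim != 2 or self.occurrence.shape[1] != len(self.items):
            raise ValidationError("occurrence matrix shape does not match catalogue")
        self.n = int(self.occurrence.shape[0])
        self._index = {item.id: j for j, item in enumerate(self.items)}
        if len(self._index) != len(self.items):
            raise ValidationError("duplicate item ids in catalogue")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(item.id for item in self.items)

    def column(self, item_id: str) -> np.ndarray:
        try:
            return self.occurrence[:, self._index[item_id]]
        except KeyError:
            raise ValidationError(f"unknown item id {item_id!r}") from None

    def contains_rows(self, s: Itemset) -> np.ndarray:
        """Boolean row mask: rows containing every item of *s*."""
        if s.k == 0:
            return np.ones(self.n, dtype=bool)
        cols = [self._index.get(i) for i in s.items]
        missing = [i for i, c in zip(s.items, cols) if c is None]
        if missing:
            raise ValidationError(f"unknown item id(s) {missing}")
        return self.occurrence[:, cols].all(axis=1)


def load_transactions(
    path: str | Path, schema: FeatureSchema | None = None
) -> TransactionTable:
    """Read a comma-separated UTF-8 table with a header row of feature names.

    Empty cells denote a missing value: the record simply contributes no
    item for that feature.  When *schema* is ``None`` it is inferred from
    the observed values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if frame.empty:
        raise ValidationError(f"{path}: no records")
    return table_from_frame(frame, schema)


def table_from_frame(
    frame: pd.DataFrame, schema: FeatureSchema | None = None
) -> TransactionTable:
    """Build a validated table from a DataFrame of strings (itemized lazily)."""
    if len(frame) == 0:
        raise ValidationError("no records")
    frame = frame.astype(str)
    records = []
    for _, row in frame.iterrows():
        rec = {f: v.strip() for f, v in row.items() if v.strip() != ""}
        records.append(rec)
    if schema is None:
        observed: dict[str, set[str]] = {str(c).strip(): set() for c in frame.columns}
        for rec in records:
            for f, v in rec.items():
                observed[str(f).strip()].add(v)
        schema = FeatureSchema.from_mapping(
            {f: vals for f, vals in observed.items() if vals}
        )
    return TransactionTable(tuple(records), schema)


def positive_value_filter(positive: str = "yes") -> Callable[[Item], bool]:
    """Item filter keeping only the risk-bearing value of binary features."""
    return lambda item: item.value == positive


def itemize(
    table: TransactionTable,
    item_filter: Callable[[Item], bool] | None = None,
) -> ItemizedDataset:
    """Expand a table into a binary occurrence matrix of feature=value items.

    One item is created per (feature, value) pair observed in the table and
    passing *item_filter* (``None`` keeps every pair).  Items of the same
    feature are mutually exclusive by construction.
    """
    seen: dict[tuple[str, str], None] = {}
    for record in table.records:
        for feature, value in record.items():
            seen.setdefault((feature, value), None)
    items = [Item(f, v) for f, v in seen]
    if item_filter is not None:
        items = [it for it in items if item_filter(it)]
    if not items:
        raise ValidationError("item filter removed every item")
    items = tuple(sorted(items, key=lambda it: it.id))
    occurrence = np.zeros((len(table), len(items)), dtype=bool)
    index = {(it.feature, it.value): j for j, it in enumerate(items)}
    for i, record in enumerate(table.records):
        for feature, value in record.items():
            j = index.get((feature, value))
            if j is not None:
                occurrence[i, j] = True
    return ItemizedDataset(items, occurrence)


def support(ds: ItemizedDataset, s: Itemset | Sequence[str]) -> float:
    """Fraction of transactions containing every item of *s* (empty set: 1)."""
    if not isinstance(s, Itemset):
        s = Itemset(s)
    if ds.n == 0:
        raise ValidationError("empty dataset")
    return float(ds.contains_rows(s).sum()) / ds.n
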