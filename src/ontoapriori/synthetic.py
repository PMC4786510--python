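"""Synthetic patient-record generator in the gastric-cancer study schema.

The real cohort behind the published rule counts is not publicly deposited,
so this module generates stand-in tables: 29 categorical risk-factor
features with the study's value ranges, independent per-feature marginals,
and optionally *planted* antecedent→consequent dependencies whose strength
is a rewrite probability (``lift``).  Everything is reproducible from a
single integer seed.

Draw order is record-major and fixed: for each record, features are drawn
in schema order, then planted rules are applied in list order (later rules
may overwrite the consequent written by earlier ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .transactions import (
    FeatureSchema,
    Item,
    TransactionTable,
    ValidationError,
)

__all__ = ["PlantedRule", "GeneratorSpec", "default_schema", "generate"]

# The 29 risk-factor features of the gastric-cancer study, grouped into
# personal characteristics/behaviour and systemic/stomach features, with
# continuous quantities arriving pre-binned (BMI, age).
_DEFAULT_FEATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    # personal characteristics and behaviour
    ("Sex", ("male", "female")),
    ("Blood group", ("A", "B", "AB", "O")),
    ("Smoking", ("yes", "no")),
    ("Alcohol consumption", ("yes", "no")),
    ("Exposed to chemicals", ("yes", "no")),
    ("BMI", ("BMI>30", "25<BMI<29.5", "18.5<BMI<24.9", "BMI<18.5")),
    ("Motility", ("light", "medium", "high")),
    ("Age", ("<40", "41-60", ">61")),
    ("Salt consumption", ("not eat", "high", "low")),
    ("Consumption of vegetable", ("daily", "1-3 times a week", "1-3 times a month")),
    ("Consumption of smoked food", ("not eat", "1-3 times a week", "1-3 times a month")),
    ("Milk consumption", ("yes", "no")),
    ("Fast food consumption", ("not eat", "1-3 times a week", "1-3 times a month")),
    ("Consumption of fried foods", ("not eat", "1-3 times a week", "1-3 times a month")),
    ("Fruit consumption", ("daily", "1-3 times a week", "1-3 times a month")),
    ("Food storage container", ("aluminum", "plastic", "chinese", "style", "copper")),
    ("Dish cooking", ("aluminum", "teflon", "copper")),
    # systemic features and the stomach
    ("History of allergy", ("yes", "no")),
    ("Family history of cancer", ("yes", "no")),
    ("Family history of gastric cancer", ("yes", "no")),
    ("History of cardiovascular disease", ("yes", "no")),
    ("Gastric cancer", ("yes", "no")),
    ("General status of cancer", ("good", "so-so", "poor")),
    ("History of gastric reflux", ("yes", "no")),
    ("History of stomach surgery", ("yes", "no")),
    ("History of gastritis", ("yes", "no")),
    ("History of stomach infection", ("yes", "no")),
    ("Mucosa status", ("normal", "swollen", "red", "sore")),
    ("Cancer site", ("cardia", "non cardia")),
)


def default_schema() -> FeatureSchema:
    """The 29-feature study schema with its categorical value ranges."""
    return FeatureSchema(
        tuple((name, frozenset(values)) for name, values in _DEFAULT_FEATURES)
    )


def default_value_order(feature: str) -> tuple[str, ...]:
    """Deterministic value order for marginal vectors (schema order)."""
    for name, values in _DEFAULT_FEATURES:
        if name == feature:
            return values
    raise KeyError(feature)


@dataclass(frozen=True)
class PlantedRule:
    """Dependency planted into generated data.

    When every antecedent item is present in a record, the consequent
    feature's value is rewritten to the consequent value with probability
    ``lift``; lift 1.0 forces the rule to hold with confidence 1.
    """

    antecedent: tuple[Item, ...]
    consequent: Item
    lift: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lift <= 1.0):
            raise ValidationError(f"lift must be in [0, 1], got {self.lift}")
        if not self.antecedent:
            raise ValidationError("planted rule needs a nonempty antecedent")


@dataclass
class GeneratorSpec:
    """Full description of one synthetic table: schema, size, seed,
    per-feature marginals and planted rules.

    ``marginals`` maps a feature name to a probability vector over its
    values, given as an ordered mapping value → probability; features
    without an entry are drawn uniformly.
    """

    schema: FeatureSchema
    n: int
    seed: int
    marginals: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    planted_rules: Sequence[PlantedRule] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        names = set(self.schema.feature_names)
        for feature, probs in self.marginals.items():
            if feature not in names:
                raise ValidationError(f"marginal for unknown feature {feature!r}")
            allowed = self.schema.allowed_values(feature)
            unknown = set(probs) - allowed
            if unknown:
                raise ValidationError(
                    f"marginal for {feature!r} names unknown values {sorted(unknown)}"
                )
            total = float(sum(probs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"marginal for {feature!r} sums to {total}, not 1"
                )
        for rule in self.planted_rules:
            for item in (*rule.antecedent, rule.consequent):
                if item.feature not in names:
                    raise ValidationError(
                        f"planted rule references unknown feature {item.feature!r}"
                    )
                if item.value not in self.schema.allowed_values(item.feature):
                    raise ValidationError(
                        f"planted rule references unknown value "
                        f"{item.value!r} for {item.feature!r}"
                    )


def _value_distribution(
    spec: GeneratorSpec, feature: str, allowed: frozenset[str]
) -> tuple[list[str], np.ndarray]:
    probs = spec.marginals.get(feature)
    if probs is None:
        values = sorted(allowed)
        p = np.full(len(values), 1.0 / len(values))
    else:
        values = list(probs.keys())
        p = np.array([probs[v] for v in values], dtype=float)
        # values absent from the marginal get probability 0
    return values, p


def generate(spec: GeneratorSpec) -> TransactionTable:
    """Sample a transaction table per *spec*; byte-identical for equal specs."""
    rng = np.random.default_rng(spec.seed)
    per_feature = [
        (name, *_value_distribution(spec, name, values))
        for name, values in spec.schema.features
    ]
    records = []
    for _ in range(spec.n):
        record: dict[str, str] = {}
        for name, values, p in per_feature:
            idx = rng.choice(len(values), p=p)
            record[name] = values[int(idx)]
        for rule in spec.planted_rules:
            if all(record.get(it.feature) == it.value for it in rule.antecedent):
                if rule.lift >= 1.0 or rng.random() < rule.lift:
                    record[rule.consequent.feature] = rule.consequent.value
        records.append(record)
    return TransactionTable(tuple(records), spec.schema)
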