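"""Level-wise frequent-itemset mining and association-rule generation.

Two miners share one loop: classic Apriori (no ontology) and the
ontology-constrained variant, in which each level's candidates are pruned
by semantic relatedness *before* support counting — inadmissible candidates
never touch the data, which is where the method saves work and rules.

Candidate generation comes in two flavours:

* ``extend-by-item`` — each frequent (k)-itemset is unioned with every
  frequent single item it does not contain.  This mirrors the constrained
  procedure: a (k+1)-candidate may be generated even when one of its
  k-subsets is infrequent.
* ``classic-join`` — the textbook Apriori join of L_k with itself followed
  by the all-k-subsets-frequent prune.

Rules A → B are scored with support(A ∪ B) and confidence
support(A ∪ B) / support(A); both thresholds are inclusive (>=).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ontology import Ontology, RelatednessPolicy, admissibility_witness
from .transactions import Itemset, ItemizedDataset, ValidationError, support

__all__ = [
    "MiningConfig",
    "RemovedCandidate",
    "LevelAudit",
    "FrequentLevels",
    "AssociationRule",
    "RuleSet",
    "frequent_singletons",
    "generate_candidates",
    "prune_semantic",
    "mine_frequent",
    "generate_rules",
]

_EPS = 1e-9

CANDIDATE_METHODS = ("extend-by-item", "classic-join")
CONSEQUENT_MODES = ("single-item", "all-partitions")


@dataclass(frozen=True)
class MiningConfig:
    min_support: float
    min_confidence: float
    candidate_method: str = "extend-by-item"
    policy: RelatednessPolicy | None = None
    consequent_mode: str = "single-item"
    max_level: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValidationError(
                f"min_support must be in (0, 1], got {self.min_support}"
            )
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValidationError(
                f"min_confidence must be in (0, 1], got {self.min_confidence}"
            )
        if self.candidate_method not in CANDIDATE_METHODS:
            raise ValidationError(
                f"unknown candidate_method {self.candidate_method!r}"
            )
        if self.consequent_mode not in CONSEQUENT_MODES:
            raise ValidationError(
                f"unknown consequent_mode {self.consequent_mode!r}"
            )
        if self.max_level is not None and self.max_level < 1:
            raise ValidationError("max_level must be >= 1")


@dataclass(frozen=True)
class RemovedCandidate:
    """Audit entry: one candidate dropped at a level, with the reason."""

    itemset: Itemset
    reason: str  # "semantic" or "support"
    pair: tuple[str, str] | None = None  # offending feature pair (semantic)
    support: float | None = None  # measured support (support removals)

    def to_dict(self) -> dict:
        d: dict = {"itemset": list(self.itemset.items), "reason": self.reason}
        if self.pair is not None:
            d["pair"] = list(self.pair)
        if self.support is not None:
            d["support"] = self.support
        return d


@dataclass(frozen=True)
class LevelAudit:
    level: int
    candidates: tuple[Itemset, ...]
    removed: tuple[RemovedCandidate, ...]
    survivors: tuple[Itemset, ...]

    @property
    def semantic_removed(self) -> tuple[RemovedCandidate, ...]:
        return tuple(r for r in self.removed if r.reason == "semantic")

    @property
    def support_removed(self) -> tuple[RemovedCandidate, ...]:
        return tuple(r for r in self.removed if r.reason == "support")

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "candidates": [list(s.items) for s in self.candidates],
            "removed": [r.to_dict() for r in self.removed],
            "survivors": [list(s.items) for s in self.survivors],
        }


@dataclass
class FrequentLevels:
    """L1..Lk with supports, plus a per-level pruning audit trail."""

    levels: list[dict[Itemset, float]]
    audit: list[LevelAudit]
    min_support: float

    def level(self, k: int) -> dict[Itemset, float]:
        """Frequent k-itemsets with supports (empty dict past the last level)."""
        if k < 1:
            raise ValidationError("levels are 1-based")
        if k > len(self.levels):
            return {}
        return self.levels[k - 1]

    def all_frequent(self) -> dict[Itemset, float]:
        merged: dict[Itemset, float] = {}
        for lvl in self.levels:
            merged.update(lvl)
        return merged

    @property
    def depth(self) -> int:
        return len(self.levels)

    def audit_to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([a.to_dict() for a in self.audit], fh, indent=2)


@dataclass(frozen=True)
class AssociationRule:
    """A -> B with support(A ∪ B) and confidence support(A∪B)/support(A)."""

    antecedent: Itemset
    consequent: Itemset
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if self.antecedent.k == 0 or self.consequent.k == 0:
            raise ValidationError("rule sides must be nonempty")
        if set(self.antecedent.items) & set(self.consequent.items):
            raise ValidationError("rule sides must be disjoint")

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return (self.antecedent.items, self.consequent.items)

    def __str__(self) -> str:
        return (
            f"{' & '.join(self.antecedent.items)} -> "
            f"{' & '.join(self.consequent.items)}"
            f"  (support={self.support:.5f}, confidence={self.confidence:.5f})"
        )


@dataclass
class RuleSet:
    """Rules sorted by support desc, confidence desc, then canonical ids."""

    rules: tuple[AssociationRule, ...]

    def __post_init__(self) -> None:
        self.rules = tuple(
            sorted(
                self.rules,
                key=lambda r: (-r.support, -r.confidence, r.key),
            )
        )
        keys = [r.key for r in self.rules]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (antecedent, consequent) pairs")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def keys(self) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
        return {r.key for r in self.rules}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "antecedent": ["|".join(r.antecedent.items) for r in self.rules],
                "consequent": ["|".join(r.consequent.items) for r in self.rules],
                "support": [round(r.support, 5) for r in self.rules],
                "confidence": [round(r.confidence, 5) for r in self.rules],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_frame().to_dict(orient="records"), fh, indent=2)


def frequent_singletons(
    ds: ItemizedDataset, min_support: float
) -> dict[Itemset, float]:
    """Level-1 frequent itemsets: every item with support >= min_support."""
    if ds.n == 0:
        raise ValidationError("empty dataset")
    threshold = min_support * ds.n - _EPS
    out: dict[Itemset, float] = {}
    for item_id in ds.item_ids:
        count = int(ds.column(item_id).sum())
        if count >= threshold:
            out[Itemset([item_id])] = count / ds.n
    return out


def generate_candidates(
    Lk: Iterable[Itemset],
    L1: Iterable[Itemset] | Iterable[str],
    method: str = "extend-by-item",
) -> tuple[Itemset, ...]:
    """Propose (k+1)-candidates from the frequent k-itemsets.

    ``extend-by-item`` unions each itemset of *Lk* with every frequent
    single item not already in it; ``classic-join`` is the textbook join
    of L_k with itself plus the all-k-subsets-frequent prune.  Unions that
    would put two values of one feature in a candidate are skipped.
    """
    Lk = list(Lk)
    if method == "extend-by-item":
        item_ids = [
            s.items[0] if isinstance(s, Itemset) else s for s in L1
        ]
        seen: dict[tuple[str, ...], Itemset] = {}
        for s in Lk:
            for item_id in item_ids:
                if item_id in s:
                    continue
                try:
                    cand = s.union([item_id])
                except ValidationError:
                    continue  # two values of the same feature
                seen.setdefault(cand.items, cand)
        return tuple(sorted(seen.values()))
    if method == "classic-join":
        frequent = {s.items for s in Lk}
        seen = {}
        for a, b in combinations(sorted(Lk), 2):
            if a.items[:-1] != b.items[:-1]:
                continue
            try:
                cand = a.union(b)
            except ValidationError:
                continue
            if all(
                tuple(sub) in frequent
                for sub in combinations(cand.items, cand.k - 1)
            ):
                seen.setdefault(cand.items, cand)
        return tuple(sorted(seen.values()))
    raise ValidationError(f"unknown candidate method {method!r}")


def prune_semantic(
    cands: Iterable[Itemset],
    o: Ontology,
    p: RelatednessPolicy,
) -> tuple[tuple[Itemset, ...], tuple[RemovedCandidate, ...]]:
    """Split candidates into semantically admissible survivors and removals.

    Each removal records the first offending feature pair (all-pairs rule)
    so the audit trail can show *why* a candidate never reached support
    counting.
    """
    survivors: list[Itemset] = []
    removed: list[RemovedCandidate] = []
    for cand in cands:
        ok, witness = admissibility_witness(o, cand, p)
        if ok:
            survivors.append(cand)
        else:
            removed.append(RemovedCandidate(cand, "semantic", pair=witness))
    return tuple(survivors), tuple(removed)


def mine_frequent(
    ds: ItemizedDataset,
    cfg: MiningConfig,
    o: Ontology | None = None,
) -> FrequentLevels:
    """Run the level-wise loop: candidates → semantic prune → support filter.

    With ``cfg.policy`` set (and an ontology given) the semantic prune is
    applied to every level from 2 upward before any support is counted;
    without a policy this is classic Apriori.  Stops at the first empty
    level or at ``cfg.max_level``.
    """
    if (cfg.policy is None) != (o is None):
        raise ValidationError(
            "an ontology must be supplied exactly when cfg.policy is set"
        )
    threshold = cfg.min_support * ds.n - _EPS

    # Level 1: no semantic pruning; all observed items are candidates.
    candidates1 = tuple(Itemset([i]) for i in ds.item_ids)
    L1: dict[Itemset, float] = {}
    removed1: list[RemovedCandidate] = []
    for cand in candidates1:
        count = int(ds.column(cand.items[0]).sum())
        if count >= threshold:
            L1[cand] = count / ds.n
        else:
            removed1.append(
                RemovedCandidate(cand, "support", support=count / ds.n)
            )
    levels = [L1]
    audit = [LevelAudit(1, candidates1, tuple(removed1), tuple(L1))]

    k = 1
    while levels[-1] and (cfg.max_level is None or k < cfg.max_level):
        k += 1
        cands = generate_candidates(
            levels[-1].keys(), L1.keys(), cfg.candidate_method
        )
        removed: list[RemovedCandidate] = []
        if cfg.policy is not None and cands:
            survivors, sem_removed = prune_semantic(cands, o, cfg.policy)
            removed.extend(sem_removed)
        else:
            survivors = cands
        Lk: dict[Itemset, float] = {}
        for cand in survivors:
            count = int(ds.contains_rows(cand).sum())
            if count >= threshold:
                Lk[cand] = count / ds.n
            else:
                removed.append(
                    RemovedCandidate(cand, "support", support=count / ds.n)
                )
        audit.append(LevelAudit(k, cands, tuple(removed), tuple(Lk)))
        if not Lk:
            break
        levels.append(Lk)

    return FrequentLevels(levels, audit, cfg.min_support)


def _splits(s: Itemset, mode: str):
    if mode == "single-item":
        for item_id in s.items:
            rest = tuple(i for i in s.items if i != item_id)
            yield Itemset(rest), Itemset([item_id])
    elif mode == "all-partitions":
        for r in range(1, s.k):
            for consequent in combinations(s.items, r):
                antecedent = tuple(i for i in s.items if i not in consequent)
                yield Itemset(antecedent), Itemset(consequent)
    else:  # pragma: no cover - guarded by MiningConfig
        raise ValidationError(f"unknown consequent_mode {mode!r}")


def generate_rules(
    fl: FrequentLevels,
    ds: ItemizedDataset,
    cfg: MiningConfig,
) -> RuleSet:
    """Emit every split A → B of each frequent itemset (size >= 2) whose
    confidence support(A∪B)/support(A) meets min_confidence."""
    rules: list[AssociationRule] = []
    conf_threshold = cfg.min_confidence - 1e-12
    for s, sup in fl.all_frequent().items():
        if s.k < 2:
            continue
        union_count = int(ds.contains_rows(s).sum())
        for antecedent, consequent in _splits(s, cfg.consequent_mode):
            ante_count = int(ds.contains_rows(antecedent).sum())
            if ante_count == 0:
                continue
            confidence = union_count / ante_count
            if confidence >= conf_threshold:
                rules.append(
                    AssociationRule(antecedent, consequent, sup, confidence)
                )
    return RuleSet(tuple(rules))
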