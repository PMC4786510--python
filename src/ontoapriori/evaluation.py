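"""Classic-vs-constrained comparison reports and per-level statistics.

Produces rule-reduction reports (how many rules the semantic pruning
removed, and what fraction of the classic output that is) and per-level
candidate/frequent/rule counts suitable for support-threshold sweeps.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .mining import FrequentLevels, MiningConfig, generate_rules, mine_frequent
from .ontology import Ontology
from .transactions import ItemizedDataset, ValidationError

__all__ = [
    "ComparisonReport",
    "compare",
    "level_statistics",
    "support_sweep",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Rule counts of both miners at one (support, confidence) setting."""

    min_support: float
    min_confidence: float
    n_rules_classic: int
    n_rules_constrained: int
    n_removed: int
    pct_removed: float
    classic_seconds: float | None = None
    constrained_seconds: float | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.classic_seconds is None:
            d.pop("classic_seconds")
            d.pop("constrained_seconds")
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare(
    ds: ItemizedDataset,
    cfg: MiningConfig,
    o: Ontology,
    time_runs: bool = False,
) -> ComparisonReport:
    """Mine *ds* classically and with the ontology constraint and report
    the rule-count reduction.

    Both runs use the same candidate method and thresholds; only the
    semantic prune differs.  ``time_runs`` additionally records wall-clock
    seconds per run (hardware-dependent; informational only).
    """
    if cfg.policy is None:
        raise ValidationError("compare() needs a config with a relatedness policy")
    classic_cfg = dataclasses.replace(cfg, policy=None)

    t0 = time.perf_counter()
    classic_rules = generate_rules(
        mine_frequent(ds, classic_cfg, None), ds, classic_cfg
    )
    t1 = time.perf_counter()
    constrained_rules = generate_rules(mine_frequent(ds, cfg, o), ds, cfg)
    t2 = time.perf_counter()

    n_classic = len(classic_rules)
    n_constrained = len(constrained_rules)
    n_removed = n_classic - n_constrained
    pct = 100.0 * n_removed / n_classic if n_classic else 0.0
    return ComparisonReport(
        min_support=cfg.min_support,
        min_confidence=cfg.min_confidence,
        n_rules_classic=n_classic,
        n_rules_constrained=n_constrained,
        n_removed=n_removed,
        pct_removed=pct,
        classic_seconds=(t1 - t0) if time_runs else None,
        constrained_seconds=(t2 - t1) if time_runs else None,
    )


def level_statistics(fl: FrequentLevels, rules=None) -> pd.DataFrame:
    """Per-level candidate and frequent-itemset counts, with totals.

    Columns: level, n_candidates, n_semantic_removed, n_support_removed,
    n_frequent, and (when a rule set is given) n_rules whose full itemset
    A ∪ B has that cardinality.  The last row holds column totals.
    """
    rows = []
    for a in fl.audit:
        row = {
            "level": a.level,
            "n_candidates": len(a.candidates),
            "n_semantic_removed": len(a.semantic_removed),
            "n_support_removed": len(a.support_removed),
            "n_frequent": len(a.survivors),
        }
        if rules is not None:
            row["n_rules"] = sum(
                1
                for r in rules
                if r.antecedent.k + r.consequent.k == a.level
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    totals = frame.drop(columns="level").sum()
    totals["level"] = "total"
    return pd.concat([frame, totals.to_frame().T], ignore_index=True)


def support_sweep(
    ds: ItemizedDataset,
    cfg: MiningConfig,
    o: Ontology | None,
    supports: Sequence[float],
) -> pd.DataFrame:
    """Re-mine at each support threshold and tabulate the level statistics.

    Columns mirror the published sweep format: min_support, number of
    frequent 2-itemsets, total frequent itemsets, and rules generated.
    """
    rows = []
    for s in supports:
        run_cfg = dataclasses.replace(cfg, min_support=s)
        fl = mine_frequent(ds, run_cfg, o)
        rules = generate_rules(fl, ds, run_cfg)
        rows.append(
            {
                "min_support": s,
                "n_2_itemsets": len(fl.level(2)),
                "n_frequent_total": len(fl.all_frequent()),
                "n_rules": len(rules),
            }
        )
    return pd.DataFrame(rows)
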