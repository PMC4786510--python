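"""Domain ontology and the semantic relatedness meta-rules.

The ontology is a concept graph with typed edges (IS-A, cause, attribute-of,
part-of) and a map from dataset features to concepts.  Three meta-rules
decide whether two features are semantically related:

* **direct** — an IS-A or cause edge joins their concepts (either direction);
* **indirect** — a path of at most ``max_intermediates`` intermediate
  concepts joins them (default one intermediate, e.g. a diet item and the
  disease linked through the risk-factor category);
* **cohort** — their concepts share an immediate parent category, so they
  belong to the same group of risk factors.

Explicit per-pair overrides (from a policy or from the ontology file)
take precedence over graph-derived relatedness.  Relatedness is symmetric
and reflexive by definition; edge direction is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

from .transactions import Itemset, ValidationError

__all__ = [
    "RELATION_TYPES",
    "Concept",
    "OntologyEdge",
    "Ontology",
    "RelatednessPolicy",
    "load_ontology",
    "directly_related",
    "indirectly_related",
    "cohort_related",
    "related",
    "semantically_admissible",
]

RELATION_TYPES = ("IS-A", "cause", "attribute-of", "part-of")

#: Relation types that make a pair *directly* related.
DIRECT_RELATIONS = ("IS-A", "cause")


@dataclass(frozen=True)
class Concept:
    name: str
    kind: str = "class"  # "class" or "feature-attribute"


@dataclass(frozen=True)
class OntologyEdge:
    source: str
    target: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATION_TYPES:
            raise ValidationError(
                f"unknown relation {self.relation!r}; expected one of {RELATION_TYPES}"
            )


def _pair(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


@dataclass
class Ontology:
    """Concept graph, feature→concept map, and optional pair overrides."""

    concepts: tuple[Concept, ...]
    edges: tuple[OntologyEdge, ...]
    feature_map: dict[str, str]
    overrides: dict[frozenset[str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.concepts]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate concept names: {dupes}")
        known = set(names)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValidationError(
                    f"edge {e.source!r} -{e.relation}-> {e.target!r} references "
                    "an undeclared concept"
                )
        for feature, concept in self.feature_map.items():
            if concept not in known:
                raise ValidationError(
                    f"feature {feature!r} mapped to undeclared concept {concept!r}"
                )
        isa = nx.DiGraph()
        isa.add_nodes_from(known)
        isa.add_edges_from(
            (e.source, e.target) for e in self.edges if e.relation == "IS-A"
        )
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            raise ValidationError(f"IS-A relation contains a cycle: {cycle}")
        self._isa = isa
        # Undirected IS-A/cause view, for direct and (default) indirect queries.
        direct = nx.Graph()
        direct.add_nodes_from(known)
        for e in self.edges:
            if e.relation in DIRECT_RELATIONS:
                direct.add_edge(e.source, e.target)
        self._direct = direct

    def concept_of(self, feature: str) -> str:
        try:
            return self.feature_map[feature]
        except KeyError:
            raise ValidationError(f"feature {feature!r} is not mapped to a concept") from None

    def parents(self, concept: str) -> set[str]:
        """Immediate IS-A parents (child -IS-A-> parent)."""
        return set(self._isa.successors(concept))

    def override_for(self, a: str, b: str) -> bool | None:
        return self.overrides.get(_pair(a, b))

    def is_total_for(self, features: Iterable[str]) -> bool:
        return all(f in self.feature_map for f in features)


@dataclass(frozen=True)
class RelatednessPolicy:
    """Which meta-rules count as 'related' and how candidates are judged.

    ``candidate_rule`` is ``"all-pairs-related"`` (every pair of items in a
    candidate must be related — anti-monotone, the default) or
    ``"any-pair-related"`` (one related pair suffices).
    ``explicit_overrides`` take precedence over both the ontology's own
    overrides and the graph.
    """

    use_direct: bool = True
    use_indirect: bool = True
    indirect_max_intermediates: int = 1
    use_cohort: bool = True
    candidate_rule: str = "all-pairs-related"
    explicit_overrides: Mapping[frozenset[str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.candidate_rule not in ("all-pairs-related", "any-pair-related"):
            raise ValidationError(
                f"unknown candidate_rule {self.candidate_rule!r}"
            )
        if self.indirect_max_intermediates < 0:
            raise ValidationError("indirect_max_intermediates must be >= 0")

    @staticmethod
    def overrides_from_pairs(
        pairs: Iterable[tuple[str, str, bool]]
    ) -> dict[frozenset[str], bool]:
        return {_pair(a, b): flag for a, b, flag in pairs}

    @classmethod
    def complete(cls, features: Iterable[str]) -> "RelatednessPolicy":
        """Every pair of the given features overridden as related."""
        feats = list(features)
        overrides = {
            _pair(a, b): True
            for i, a in enumerate(feats)
            for b in feats[i + 1 :]
        }
        return cls(explicit_overrides=overrides)

    @classmethod
    def nothing_related(cls) -> "RelatednessPolicy":
        """All meta-rules disabled and no overrides: no pair is related."""
        return cls(use_direct=False, use_indirect=False, use_cohort=False)


def trivial_ontology(features: Iterable[str]) -> Ontology:
    """One isolated concept per feature, no edges, no overrides.

    Useful as a carrier for policies whose relatedness comes entirely from
    explicit overrides (e.g. the complete or empty relatedness policies).
    """
    feats = list(dict.fromkeys(features))
    return Ontology(
        concepts=tuple(Concept(f, "feature-attribute") for f in feats),
        edges=(),
        feature_map={f: f for f in feats},
    )


def load_ontology(path: str | Path) -> Ontology:
    """Parse an ontology file (YAML) into a validated :class:`Ontology`.

    The document has up to four blocks: ``concepts`` (list of ``name`` /
    optional ``parent`` / optional ``kind``; a parent adds an IS-A edge),
    ``relations`` (list of ``[source, relation, target]`` triples),
    ``feature_map`` (feature name → concept name) and ``overrides``
    (list of ``[feature_a, feature_b, related?]`` assertions).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: ontology document must be a mapping")
    raw_concepts = doc.get("concepts") or []
    if not raw_concepts and (doc.get("relations") or doc.get("feature_map")):
        raise ValidationError(f"{path}: relations/feature_map without concepts")
    concepts: list[Concept] = []
    edges: list[OntologyEdge] = []
    for entry in raw_concepts:
        if isinstance(entry, str):
            entry = {"name": entry}
        concepts.append(Concept(entry["name"], entry.get("kind", "class")))
        parent = entry.get("parent")
        if parent is not None:
            edges.append(OntologyEdge(entry["name"], parent, "IS-A"))
    for triple in doc.get("relations") or []:
        source, relation, target = triple
        edges.append(OntologyEdge(source, target, relation))
    feature_map = dict(doc.get("feature_map") or {})
    overrides = {
        _pair(a, b): bool(flag) for a, b, flag in doc.get("overrides") or []
    }
    return Ontology(tuple(concepts), tuple(edges), feature_map, overrides)


def _graph_override(o: Ontology, a: str, b: str) -> bool | None:
    if a == b:
        return True
    return o.override_for(a, b)


def directly_related(o: Ontology, a: str, b: str) -> bool:
    """True iff an IS-A or cause edge joins the mapped concepts, either
    direction, or an override asserts relatedness.  Reflexive."""
    forced = _graph_override(o, a, b)
    if forced is not None:
        return forced
    ca, cb = o.concept_of(a), o.concept_of(b)
    return ca == cb or o._direct.has_edge(ca, cb)


def indirectly_related(
    o: Ontology,
    a: str,
    b: str,
    max_intermediates: int = 1,
    edge_types: tuple[str, ...] = DIRECT_RELATIONS,
) -> bool:
    """True iff the mapped concepts are joined by an undirected path with at
    most *max_intermediates* intermediate concepts over the enabled edge
    types (default IS-A and cause, like the direct rule).

    ``max_intermediates=0`` therefore reduces to :func:`directly_related`.
    """
    forced = _graph_override(o, a, b)
    if forced is not None:
        return forced
    ca, cb = o.concept_of(a), o.concept_of(b)
    if ca == cb:
        return True
    if edge_types == DIRECT_RELATIONS:
        graph = o._direct
    else:
        graph = nx.Graph()
        graph.add_nodes_from(c.name for c in o.concepts)
        graph.add_edges_from(
            (e.source, e.target) for e in o.edges if e.relation in edge_types
        )
    cutoff = max_intermediates + 1  # path length in edges
    reachable = nx.single_source_shortest_path_length(graph, ca, cutoff=cutoff)
    return cb in reachable


def cohort_related(o: Ontology, a: str, b: str) -> bool:
    """True iff the mapped concepts share an immediate IS-A parent category."""
    if a == b:
        return True
    ca, cb = o.concept_of(a), o.concept_of(b)
    if ca == cb:
        return True
    return bool(o.parents(ca) & o.parents(cb))


def related(o: Ontology, a: str, b: str, p: RelatednessPolicy) -> bool:
    """Disjunction of the enabled meta-rules after applying overrides.

    Policy overrides win over ontology-file overrides, which win over the
    graph.  Symmetric and reflexive for every policy.
    """
    if a == b:
        return True
    key = _pair(a, b)
    if key in p.explicit_overrides:
        return bool(p.explicit_overrides[key])
    forced = o.override_for(a, b)
    if forced is not None:
        return forced
    # Validate mapping up front so disabled-rule policies still error on
    # unknown features.
    o.concept_of(a), o.concept_of(b)
    if p.use_direct and directly_related(o, a, b):
        return True
    if p.use_indirect and indirectly_related(
        o, a, b, p.indirect_max_intermediates
    ):
        return True
    if p.use_cohort and cohort_related(o, a, b):
        return True
    return False


def semantically_admissible(
    o: Ontology, s: Itemset, p: RelatednessPolicy
) -> bool:
    """Judge a candidate itemset (|s| >= 2) by pairwise feature relatedness.

    Under ``all-pairs-related`` every unordered pair of the itemset's
    features must be related; under ``any-pair-related`` one related pair
    suffices.  Admissibility applies from level 2 upward, so singletons are
    rejected as a contract violation.
    """
    passing, _ = admissibility_witness(o, s, p)
    return passing


def admissibility_witness(
    o: Ontology, s: Itemset, p: RelatednessPolicy
) -> tuple[bool, tuple[str, str] | None]:
    """Like :func:`semantically_admissible` but also return a witness pair:
    the first unrelated pair under all-pairs (None when admissible), or a
    related pair under any-pair (None when inadmissible)."""
    if s.k < 2:
        raise ValidationError(
            "semantic admissibility applies to itemsets of size >= 2"
        )
    features = s.features
    if p.candidate_rule == "all-pairs-related":
        for i, fa in enumerate(features):
            for fb in features[i + 1 :]:
                if not related(o, fa, fb, p):
                    return False, (fa, fb)
        return True, None
    for i, fa in enumerate(features):
        for fb in features[i + 1 :]:
            if related(o, fa, fb, p):
                return True, (fa, fb)
    return False, None
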