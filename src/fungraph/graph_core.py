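"""Typed heterogeneous property graph ("information network").

Nodes are *concepts* — typed biological entities (genes, ontology terms,
publications, proteins, metabolites ...) carrying accessions, synonyms,
free-form attributes and data-source provenance.  Edges are *relations* —
typed, directed, attributed links between two concepts (``encodes``,
``annotated_to``, ``is_a``, ``neighbor_of``, ``mentions`` ...).

External identity of a concept is the pair ``(concept class, primary
accession)``; internal ids are opaque sequential integers.  Adding a concept
whose identity pair already exists is an upsert: names, attributes and
evidence are unioned onto the existing concept.  Relations are unique per
``(source, target, type)`` triple and likewise upsert.

The container supports induced subgraphs (for running expensive operations
on a selection) and merge-back of such temporary subgraphs into the main
graph, matched by accession, so that a failed or repeated operation never
corrupts or duplicates the main network.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "GraphError",
    "UnknownClassError",
    "ValidationError",
    "DanglingEndpointError",
    "MissingConceptError",
    "RegistryError",
    "ConceptClass",
    "ConceptClassRegistry",
    "default_registry",
    "Concept",
    "Relation",
    "MetaLegend",
    "MergeReport",
    "InformationGraph",
    "merge_into",
]


class GraphError(Exception):
    """Base class for information-graph errors."""


class UnknownClassError(GraphError):
    """A concept class is not registered."""


class ValidationError(GraphError):
    """Invalid concept or relation payload."""


class DanglingEndpointError(GraphError):
    """A relation references a concept id absent from the graph."""


class MissingConceptError(GraphError):
    """A requested concept id does not exist."""


class RegistryError(GraphError):
    """Two class registries disagree on an existing class."""


# Concept classes seeded into every default registry.  GeneAfu / GeneScer
# (orthologous genes in A. fumigatus / S. cerevisiae) specialise Gene.
_DEFAULT_CLASSES: tuple[tuple[str, str | None], ...] = (
    ("Gene", None),
    ("GO", None),
    ("FunCat", None),
    ("Pathway", None),
    ("Publication", None),
    ("Metabolite", None),
    ("Reaction", None),
    ("GeneAfu", "Gene"),
    ("GeneScer", "Gene"),
    ("Protein", None),
    ("ProteinDomain", None),
)


@dataclass(frozen=True)
class ConceptClass:
    name: str
    parent: str | None = None


class ConceptClassRegistry:
    """Single-inheritance hierarchy of concept classes."""

    def __init__(self) -> None:
        self._classes: dict[str, ConceptClass] = {}

    def register(self, name: str, parent: str | None = None) -> ConceptClass:
        if not name:
            raise ValidationError("concept class name must be non-empty")
        existing = self._classes.get(name)
        if existing is not None:
            if existing.parent != parent:
                raise RegistryError(
                    f"class {name!r} already registered with parent "
                    f"{existing.parent!r}, not {parent!r}"
                )
            return existing
        if parent is not None and parent not in self._classes:
            raise UnknownClassError(f"parent class {parent!r} not registered")
        cc = ConceptClass(name, parent)
        self._classes[name] = cc
        return cc

    def __contains__(self, name: str) -> bool:
        return name in self._classes

    def __iter__(self) -> Iterator[ConceptClass]:
        return iter(self._classes.values())

    def get(self, name: str) -> ConceptClass:
        try:
            return self._classes[name]
        except KeyError:
            raise UnknownClassError(f"concept class {name!r} not registered") from None

    def ancestors(self, name: str) -> list[str]:
        """Ancestor class names of ``name``, nearest first (excl. itself)."""
        out: list[str] = []
        cur = self.get(name).parent
        while cur is not None:
            out.append(cur)
            cur = self.get(cur).parent
        return out

    def is_a(self, name: str, ancestor: str) -> bool:
        """True if ``name`` equals ``ancestor`` or descends from it."""
        return name == ancestor or ancestor in self.ancestors(name)

    def copy(self) -> "ConceptClassRegistry":
        new = ConceptClassRegistry()
        new._classes = dict(self._classes)
        return new

    def merge_from(self, other: "ConceptClassRegistry") -> None:
        """Adopt classes from ``other``; conflicting parents raise."""
        # register in dependency order so parents exist first
        pending = list(other)
        while pending:
            progressed = False
            rest = []
            for cc in pending:
                if cc.parent is None or cc.parent in self._classes:
                    self.register(cc.name, cc.parent)
                    progressed = True
                else:
                    rest.append(cc)
            if not progressed:  # parent cycle can't occur; unreachable parents
                raise RegistryError("unresolvable class hierarchy in merge")
            pending = rest


def default_registry() -> ConceptClassRegistry:
    reg = ConceptClassRegistry()
    for name, parent in _DEFAULT_CLASSES:
        reg.register(name, parent)
    return reg


AttributeValue = str | int | float | list


@dataclass
class Concept:
    id: int
    cls: str
    accession: str
    source: str = ""
    names: list[str] = field(default_factory=list)
    attributes: dict[str, AttributeValue] = field(default_factory=dict)
    evidence: list[str] = field(default_factory=list)

    @property
    def preferred_name(self) -> str:
        return self.names[0] if self.names else self.accession

    @property
    def synonyms(self) -> list[str]:
        return self.names[1:]


@dataclass
class Relation:
    id: int
    source_id: int
    target_id: int
    rel_type: str
    attributes: dict[str, AttributeValue] = field(default_factory=dict)
    evidence: list[str] = field(default_factory=list)


@dataclass
class MetaLegend:
    """Schema summary: concepts per class, relations per (class, type, class)."""

    concept_counts: dict[str, int]
    relation_counts: dict[tuple[str, str, str], int]

    @property
    def n_concepts(self) -> int:
        return sum(self.concept_counts.values())

    @property
    def n_relations(self) -> int:
        return sum(self.relation_counts.values())


@dataclass
class MergeReport:
    concepts_added: int = 0
    relations_added: int = 0
    concepts_updated: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.concepts_added, self.relations_added, self.concepts_updated)


def _union_attributes(dest: dict, new: Mapping) -> bool:
    """Union ``new`` into ``dest``; conflicting values kept under suffixed
    keys (``key.2``, ``key.3`` ...).  Returns True if anything changed."""
    changed = False
    for key, value in new.items():
        if key not in dest:
            dest[key] = value
            changed = True
            continue
        # collect existing values for this key (base + suffixed)
        existing = [dest[key]]
        n = 2
        while f"{key}.{n}" in dest:
            existing.append(dest[f"{key}.{n}"])
            n += 1
        if any(value == e for e in existing):
            continue
        dest[f"{key}.{n}"] = value
        changed = True
    return changed


def _union_list(dest: list, new: Iterable) -> bool:
    changed = False
    seen = set(dest)
    for item in new:
        if item not in seen:
            dest.append(item)
            seen.add(item)
            changed = True
    return changed


class InformationGraph:
    """Mutable container of concepts and relations with accession indexing."""

    def __init__(self, registry: ConceptClassRegistry | None = None) -> None:
        self.registry = registry.copy() if registry is not None else default_registry()
        self._concepts: dict[int, Concept] = {}
        self._relations: dict[int, Relation] = {}
        self._acc_index: dict[tuple[str, str], int] = {}
        self._rel_index: dict[tuple[int, int, str], int] = {}
        self._next_cid = 1
        self._next_rid = 1

    # ------------------------------------------------------------------ basic
    @property
    def n_concepts(self) -> int:
        return len(self._concepts)

    @property
    def n_relations(self) -> int:
        return len(self._relations)

    def concepts(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    def relations(self) -> Iterator[Relation]:
        return iter(self._relations.values())

    def concept(self, cid: int) -> Concept:
        try:
            return self._concepts[cid]
        except KeyError:
            raise MissingConceptError(f"no concept with id {cid}") from None

    def has_concept(self, cid: int) -> bool:
        return cid in self._concepts

    def find(self, cls: str, accession: str) -> int | None:
        return self._acc_index.get((cls, accession))

    def has_relation(self, source_id: int, target_id: int, rel_type: str) -> bool:
        return (source_id, target_id, rel_type) in self._rel_index

    def get_relation(self, source_id: int, target_id: int, rel_type: str) -> Relation:
        rid = self._rel_index.get((source_id, target_id, rel_type))
        if rid is None:
            raise MissingConceptError(
                f"no relation ({source_id}, {target_id}, {rel_type!r})"
            )
        return self._relations[rid]

    def concepts_of_class(self, cls: str, include_subclasses: bool = True) -> list[Concept]:
        if include_subclasses:
            return [c for c in self._concepts.values() if self.registry.is_a(c.cls, cls)]
        return [c for c in self._concepts.values() if c.cls == cls]

    def relations_of(self, cid: int, rel_type: str | None = None,
                     direction: str = "both") -> list[Relation]:
        out = []
        for rel in self._relations.values():
            if rel_type is not None and rel.rel_type != rel_type:
                continue
            if direction in ("out", "both") and rel.source_id == cid:
                out.append(rel)
            elif direction in ("in", "both") and rel.target_id == cid:
                out.append(rel)
        return out

    # -------------------------------------------------------------- mutation
    def add_concept(self, cls: str, accession: str,
                    names: Sequence[str] | None = None,
                    attributes: Mapping[str, AttributeValue] | None = None,
                    evidence: Sequence[str] | None = None,
                    source: str = "") -> int:
        """Add or upsert a concept; returns its (stable) internal id."""
        if cls not in self.registry:
            raise UnknownClassError(f"concept class {cls!r} not registered")
        if not accession:
            raise ValidationError("primary accession must be non-empty")
        names = list(names) if names else [accession]
        cid = self._acc_index.get((cls, accession))
        if cid is not None:
            c = self._concepts[cid]
            _union_list(c.names, names)
            if attributes:
                _union_attributes(c.attributes, attributes)
            if evidence:
                _union_list(c.evidence, evidence)
            if source and not c.source:
                c.source = source
            return cid
        cid = self._next_cid
        self._next_cid += 1
        self._concepts[cid] = Concept(
            id=cid, cls=cls, accession=accession, source=source,
            names=names, attributes=dict(attributes or {}),
            evidence=list(evidence or []),
        )
        self._acc_index[(cls, accession)] = cid
        return cid

    def set_attribute(self, cid: int, key: str, value: AttributeValue) -> None:
        """Overwrite a single attribute (no union/suffix semantics)."""
        self.concept(cid).attributes[key] = value

    def add_relation(self, source_id: int, target_id: int, rel_type: str,
                     attributes: Mapping[str, AttributeValue] | None = None,
                     evidence: Sequence[str] | None = None) -> int:
        if source_id not in self._concepts:
            raise DanglingEndpointError(f"source concept {source_id} not in graph")
        if target_id not in self._concepts:
            raise DanglingEndpointError(f"target concept {target_id} not in graph")
        if not rel_type:
            raise ValidationError("relation type must be non-empty")
        key = (source_id, target_id, rel_type)
        rid = self._rel_index.get(key)
        if rid is not None:
            rel = self._relations[rid]
            if attributes:
                _union_attributes(rel.attributes, attributes)
            if evidence:
                _union_list(rel.evidence, evidence)
            return rid
        rid = self._next_rid
        self._next_rid += 1
        self._relations[rid] = Relation(
            id=rid, source_id=source_id, target_id=target_id, rel_type=rel_type,
            attributes=dict(attributes or {}), evidence=list(evidence or []),
        )
        self._rel_index[key] = rid
        return rid

    # ------------------------------------------------------------- summaries
    def meta_legend(self) -> MetaLegend:
        ccounts: Counter = Counter(c.cls for c in self._concepts.values())
        rcounts: Counter = Counter(
            (self._concepts[r.source_id].cls, r.rel_type, self._concepts[r.target_id].cls)
            for r in self._relations.values()
        )
        return MetaLegend(dict(ccounts), dict(rcounts))

    def audit(self) -> list[str]:
        """Structural consistency check; returns a list of problems (empty = ok)."""
        problems = []
        for rel in self._relations.values():
            if rel.source_id not in self._concepts:
                problems.append(f"relation {rel.id}: dangling source {rel.source_id}")
            if rel.target_id not in self._concepts:
                problems.append(f"relation {rel.id}: dangling target {rel.target_id}")
        for (cls, acc), cid in self._acc_index.items():
            c = self._concepts.get(cid)
            if c is None or c.cls != cls or c.accession != acc:
                problems.append(f"accession index stale for ({cls}, {acc})")
        if len(self._acc_index) != len(self._concepts):
            problems.append("accession index size mismatch")
        for c in self._concepts.values():
            if not c.names:
                problems.append(f"concept {c.id}: empty name list")
        legend = self.meta_legend()
        if legend.n_concepts != self.n_concepts:
            problems.append("meta-legend concept count mismatch")
        if legend.n_relations != self.n_relations:
            problems.append("meta-legend relation count mismatch")
        return problems

    # ------------------------------------------------------------- subgraphs
    def induce_subgraph(self, concept_ids: Iterable[int],
                        with_relations: bool = True) -> "InformationGraph":
        """Deep-copied subgraph of the selected concepts (ids preserved).

        Contains exactly the selected concepts and, if ``with_relations``,
        all and only relations with both endpoints selected.
        """
        ids = set(concept_ids)
        for cid in ids:
            if cid not in self._concepts:
                raise MissingConceptError(f"no concept with id {cid}")
        sub = InformationGraph(self.registry)
        for cid in sorted(ids):
            c = self._concepts[cid]
            sub._concepts[cid] = Concept(
                id=cid, cls=c.cls, accession=c.accession, source=c.source,
                names=list(c.names), attributes=json.loads(json.dumps(c.attributes)),
                evidence=list(c.evidence),
            )
            sub._acc_index[(c.cls, c.accession)] = cid
        sub._next_cid = self._next_cid
        if with_relations:
            for rel in self._relations.values():
                if rel.source_id in ids and rel.target_id in ids:
                    sub._relations[rel.id] = Relation(
                        id=rel.id, source_id=rel.source_id, target_id=rel.target_id,
                        rel_type=rel.rel_type,
                        attributes=json.loads(json.dumps(rel.attributes)),
                        evidence=list(rel.evidence),
                    )
                    sub._rel_index[(rel.source_id, rel.target_id, rel.rel_type)] = rel.id
            sub._next_rid = self._next_rid
        return sub

    def copy(self) -> "InformationGraph":
        return self.induce_subgraph(self._concepts.keys(), with_relations=True)

    def _replace_state_from(self, other: "InformationGraph") -> None:
        """Adopt another graph's entire state (used for atomic main-mode ops)."""
        self.registry = other.registry
        self._concepts = other._concepts
        self._relations = other._relations
        self._acc_index = other._acc_index
        self._rel_index = other._rel_index
        self._next_cid = other._next_cid
        self._next_rid = other._next_rid

    # ---------------------------------------------------------- serialization
    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in sorted(self._concepts.values(), key=lambda c: c.id):
                fh.write(json.dumps({
                    "kind": "concept", "id": c.id, "cls": c.cls,
                    "accession": c.accession, "source": c.source,
                    "names": c.names, "attributes": c.attributes,
                    "evidence": c.evidence,
                }, sort_keys=True) + "\n")
            for r in sorted(self._relations.values(), key=lambda r: r.id):
                fh.write(json.dumps({
                    "kind": "relation", "id": r.id, "source_id": r.source_id,
                    "target_id": r.target_id, "rel_type": r.rel_type,
                    "attributes": r.attributes, "evidence": r.evidence,
                }, sort_keys=True) + "\n")

    def serialize(self) -> str:
        """Canonical string form (used for byte-identity isolation checks)."""
        lines = []
        for c in sorted(self._concepts.values(), key=lambda c: c.id):
            lines.append(json.dumps({
                "kind": "concept", "id": c.id, "cls": c.cls,
                "accession": c.accession, "source": c.source, "names": c.names,
                "attributes": c.attributes, "evidence": c.evidence,
            }, sort_keys=True))
        for r in sorted(self._relations.values(), key=lambda r: r.id):
            lines.append(json.dumps({
                "kind": "relation", "id": r.id, "source_id": r.source_id,
                "target_id": r.target_id, "rel_type": r.rel_type,
                "attributes": r.attributes, "evidence": r.evidence,
            }, sort_keys=True))
        return "\n".join(lines)

    @classmethod
    def from_jsonl(cls, path, registry: ConceptClassRegistry | None = None
                   ) -> "InformationGraph":
        graph = cls(registry)
        concepts: list[dict] = []
        relations: list[dict] = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValidationError(f"line {lineno}: invalid JSON: {exc}") from exc
                kind = obj.get("kind")
                if kind == "concept":
                    concepts.append(obj)
                elif kind == "relation":
                    relations.append(obj)
                else:
                    raise ValidationError(f"line {lineno}: unknown kind {kind!r}")
        id_map: dict[int, int] = {}
        for obj in concepts:
            if obj["cls"] not in graph.registry:
                graph.registry.register(obj["cls"])
            cid = graph.add_concept(
                obj["cls"], obj["accession"], names=obj.get("names"),
                attributes=obj.get("attributes"), evidence=obj.get("evidence"),
                source=obj.get("source", ""),
            )
            id_map[obj["id"]] = cid
        for obj in relations:
            graph.add_relation(
                id_map[obj["source_id"]], id_map[obj["target_id"]],
                obj["rel_type"], attributes=obj.get("attributes"),
                evidence=obj.get("evidence"),
            )
        return graph

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for c in self._concepts.values():
            g.add_node(c.id, cls=c.cls, accession=c.accession,
                       name=c.preferred_name)
        for r in self._relations.values():
            g.add_edge(r.source_id, r.target_id, key=r.rel_type,
                       rel_type=r.rel_type)
        return g

    def to_graphml(self, path) -> None:
        g = nx.MultiDiGraph()
        for c in self._concepts.values():
            attrs = {k: (json.dumps(v) if isinstance(v, list) else v)
                     for k, v in c.attributes.items()}
            g.add_node(c.id, cls=c.cls, accession=c.accession,
                       name=c.preferred_name, **attrs)
        for r in self._relations.values():
            attrs = {k: (json.dumps(v) if isinstance(v, list) else v)
                     for k, v in r.attributes.items()}
            g.add_edge(r.source_id, r.target_id, key=r.rel_type,
                       rel_type=r.rel_type, **attrs)
        nx.write_graphml(g, path)


def merge_into(main: InformationGraph, temp: InformationGraph) -> MergeReport:
    """Merge a temporary subgraph back into the main graph.

    Concepts are matched by ``(class, accession)``; matched concepts receive
    the attribute/name/evidence union, new concepts are created, and all
    temp relations are remapped onto main ids.  Idempotent: merging the same
    temp twice adds nothing on the second pass.
    """
    main.registry.merge_from(temp.registry)
    report = MergeReport()
    id_map: dict[int, int] = {}
    for c in sorted(temp.concepts(), key=lambda c: c.id):
        existing = main.find(c.cls, c.accession)
        if existing is None:
            cid = main.add_concept(c.cls, c.accession, names=c.names,
                                   attributes=c.attributes, evidence=c.evidence,
                                   source=c.source)
            report.concepts_added += 1
        else:
            target = main.concept(existing)
            changed = _union_list(target.names, c.names)
            changed |= _union_attributes(target.attributes, c.attributes)
            changed |= _union_list(target.evidence, c.evidence)
            if changed:
                report.concepts_updated += 1
            cid = existing
        id_map[c.id] = cid
    for r in sorted(temp.relations(), key=lambda r: r.id):
        src, tgt = id_map[r.source_id], id_map[r.target_id]
        if not main.has_relation(src, tgt, r.rel_type):
            report.relations_added += 1
        main.add_relation(src, tgt, r.rel_type, attributes=r.attributes,
                          evidence=r.evidence)
    return report
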