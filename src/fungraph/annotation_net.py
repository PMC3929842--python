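"""Annotation-oriented subnetworks over the ontology DAG.

Given a set of genes (e.g. the strong DEGs of one contrast), extract the
genes, every ontology term directly annotated to them, and the full
ancestor closure of those terms up to the namespace root, preserving the
is_a / part_of hierarchy.  The closure goes upward only: terms annotated
to none of the genes are excluded even when they descend from included
ancestors, so every retained term lies on a path from an annotation of a
retained gene to the root.

Top-level functional categories (direct children of the namespace root)
summarise the gene set; a gene annotated at several hierarchy levels
counts toward every category it reaches, so percentages may sum above 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_core import InformationGraph
from .io_formats import HIERARCHY_RELS

__all__ = [
    "NamespaceError",
    "CategoryRow",
    "ComponentSummary",
    "annotation_subnetwork",
    "category_summary",
    "rank_components",
]


class NamespaceError(Exception):
    """No ontology terms carry the requested namespace."""


@dataclass(frozen=True)
class CategoryRow:
    category: str        # preferred name of the depth-1 term
    gene_count: int
    percentage: float


@dataclass(frozen=True)
class ComponentSummary:
    n_concepts: int
    n_relations: int
    top_class: str
    min_accession: str


def _namespace_terms(graph: InformationGraph, namespace: str) -> set[int]:
    ids = {c.id for c in graph.concepts()
           if c.attributes.get("namespace") == namespace}
    if not ids:
        raise NamespaceError(f"no ontology terms with namespace {namespace!r}")
    return ids


def _parent_adjacency(graph: InformationGraph, term_ids: set[int]
                      ) -> dict[int, set[int]]:
    """child -> parents over hierarchy relations within term_ids."""
    parents: dict[int, set[int]] = {t: set() for t in term_ids}
    for rel in graph.relations():
        if (rel.rel_type in HIERARCHY_RELS
                and rel.source_id in term_ids and rel.target_id in term_ids):
            parents[rel.source_id].add(rel.target_id)
    return parents


def _ancestor_closure(seeds: set[int], parents: dict[int, set[int]]) -> set[int]:
    closed = set(seeds)
    frontier = list(seeds)
    while frontier:
        node = frontier.pop()
        for p in parents.get(node, ()):
            if p not in closed:
                closed.add(p)
                frontier.append(p)
    return closed


def annotation_subnetwork(graph: InformationGraph, gene_set, namespace: str
                          ) -> InformationGraph:
    """Induce genes + directly annotated terms + their ancestor closure.

    ``gene_set`` holds gene accessions; genes absent from the graph are
    ignored.  Only ``annotated_to`` and hierarchy relations survive in the
    result.  An empty gene set yields an empty graph.
    """
    term_ids = _namespace_terms(graph, namespace)
    gene_ids = set()
    for acc in gene_set:
        cid = graph.find("Gene", acc)
        if cid is not None:
            gene_ids.add(cid)
    seeds = set()
    for rel in graph.relations():
        if (rel.rel_type == "annotated_to" and rel.source_id in gene_ids
                and rel.target_id in term_ids):
            seeds.add(rel.target_id)
    if not gene_ids:
        return InformationGraph(graph.registry)
    closed_terms = _ancestor_closure(seeds, _parent_adjacency(graph, term_ids))
    sub = graph.induce_subgraph(gene_ids | closed_terms, with_relations=True)
    keep = set(HIERARCHY_RELS) | {"annotated_to"}
    for rel in list(sub.relations()):
        if rel.rel_type not in keep:
            sub._relations.pop(rel.id)
            sub._rel_index.pop((rel.source_id, rel.target_id, rel.rel_type))
    return sub


def _roots_and_parents(sub: InformationGraph) -> tuple[set[int], dict[int, set[int]]]:
    term_ids = {c.id for c in sub.concepts() if "namespace" in c.attributes}
    parents = _parent_adjacency(sub, term_ids)
    roots = {t for t in term_ids if not parents[t]}
    return roots, parents


def category_summary(sub: InformationGraph,
                     category_map: dict[str, str] | None = None
                     ) -> list[CategoryRow]:
    """Summarise a subnetwork by top-level categories.

    Depth-1 categories are the direct children of the namespace root(s) in
    the subnetwork.  A gene counts toward category C iff one of its
    annotation terms is C or has C among its ancestors; each gene counts at
    most once per category.  Percentages are of the subnetwork's gene set.
    ``category_map`` optionally renames/merges categories (term name ->
    category label).  Rows sort by gene_count descending, then name.
    """
    genes = sub.concepts_of_class("Gene")
    if not genes:
        return []
    roots, parents = _roots_and_parents(sub)
    depth1 = {child for child, ps in parents.items() if ps & roots}
    # per-gene annotation seeds
    gene_terms: dict[int, set[int]] = {g.id: set() for g in genes}
    for rel in sub.relations():
        if rel.rel_type == "annotated_to" and rel.source_id in gene_terms:
            gene_terms[rel.source_id].add(rel.target_id)
    counts: dict[str, int] = {}
    for gid, seeds in gene_terms.items():
        reached = _ancestor_closure(seeds, parents)
        cats = set()
        for t in reached & depth1:
            name = sub.concept(t).preferred_name
            if category_map:
                name = category_map.get(name, name)
            cats.add(name)
        for name in cats:
            counts[name] = counts.get(name, 0) + 1
    n_genes = len(genes)
    rows = [CategoryRow(name, n, round(100.0 * n / n_genes, 10))
            for name, n in counts.items()]
    rows.sort(key=lambda r: (-r.gene_count, r.category))
    return rows


def rank_components(graph: InformationGraph) -> list[ComponentSummary]:
    """Weakly connected components, largest first.

    Ties break by the smallest member accession.  ``top_class`` is the most
    frequent concept class in the component (ties by class name).
    """
    g = nx.Graph()
    for c in graph.concepts():
        g.add_node(c.id)
    for rel in graph.relations():
        g.add_edge(rel.source_id, rel.target_id)
    summaries = []
    for comp in nx.connected_components(g):
        n_rel = sum(1 for rel in graph.relations()
                    if rel.source_id in comp and rel.target_id in comp)
        classes: dict[str, int] = {}
        accs = []
        for cid in comp:
            c = graph.concept(cid)
            classes[c.cls] = classes.get(c.cls, 0) + 1
            accs.append(c.accession)
        top = sorted(classes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        summaries.append(ComponentSummary(
            n_concepts=len(comp), n_relations=n_rel, top_class=top,
            min_accession=min(accs)))
    summaries.sort(key=lambda s: (-s.n_concepts, s.min_accession))
    return summaries
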