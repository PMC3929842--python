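"""Annotation subnetworks: ancestor-closure correctness against a BFS
oracle, category summaries, and component ranking."""

import random

import pytest

from fungraph.annotation_net import (NamespaceError, annotation_subnetwork,
                                     category_summary, rank_components)
from fungraph.graph_core import InformationGraph


def _ontology_graph(edges, genes, annotations, namespace="biological_process"):
    """edges: (child, parent, rel); annotations: gene -> [terms]."""
    g = InformationGraph()
    terms = {t for c, p, _ in edges for t in (c, p)}
    terms |= {t for ts in annotations.values() for t in ts}
    tids = {}
    for t in sorted(terms):
        tids[t] = g.add_concept("GO", t, names=[f"name {t}"])
        g.set_attribute(tids[t], "namespace", namespace)
    for child, parent, rel in edges:
        g.add_relation(tids[child], tids[parent], rel)
    gids = {}
    for gene in genes:
        gids[gene] = g.add_concept("Gene", gene)
    for gene, ts in annotations.items():
        for t in ts:
            g.add_relation(gids[gene], tids[t], "annotated_to")
    return g


def bfs_ancestor_closure(edges, seeds):
    """Oracle: breadth-first upward closure over the raw edge list."""
    parents = {}
    for child, parent, _ in edges:
        parents.setdefault(child, set()).add(parent)
    closed = set(seeds)
    frontier = list(seeds)
    while frontier:
        node = frontier.pop(0)
        for p in parents.get(node, ()):
            if p not in closed:
                closed.add(p)
                frontier.append(p)
    return closed


class TestSubnetwork:
    def test_chain_closure(self):
        edges = [("A1", "A", "is_a"), ("A", "R", "is_a")]
        g = _ontology_graph(edges, ["g"], {"g": ["A1"]})
        sub = annotation_subnetwork(g, {"g"}, "biological_process")
        assert sub.n_concepts == 4  # g, A1, A, R
        assert {c.accession for c in sub.concepts()} == {"g", "A1", "A", "R"}

    def test_empty_gene_set(self):
        g = _ontology_graph([("A", "R", "is_a")], [], {})
        sub = annotation_subnetwork(g, set(), "biological_process")
        assert sub.n_concepts == 0

    def test_multi_level_annotation_preserved(self):
        # a gene annotated at two hierarchy levels keeps both edges
        edges = [("low", "high", "is_a"), ("high", "R", "is_a")]
        g = _ontology_graph(edges, ["g"], {"g": ["low", "high"]})
        sub = annotation_subnetwork(g, {"g"}, "biological_process")
        gid = sub.find("Gene", "g")
        assert sub.has_relation(gid, sub.find("GO", "low"), "annotated_to")
        assert sub.has_relation(gid, sub.find("GO", "high"), "annotated_to")

    def test_unknown_namespace_rejected(self):
        g = _ontology_graph([("A", "R", "is_a")], ["g"], {"g": ["A"]})
        with pytest.raises(NamespaceError):
            annotation_subnetwork(g, {"g"}, "cellular_component")

    def test_unannotated_descendants_excluded(self):
        edges = [("used", "R", "is_a"), ("unused", "R", "is_a")]
        g = _ontology_graph(edges, ["g"], {"g": ["used"]})
        sub = annotation_subnetwork(g, {"g"}, "biological_process")
        assert sub.find("GO", "unused") is None

    def test_closure_matches_bfs_oracle_on_random_dags(self):
        rng = random.Random(77)
        for trial in range(25):
            n_terms = rng.randint(2, 25)
            terms = [f"T{i}" for i in range(n_terms)]
            edges = []
            for i in range(1, n_terms):
                parent = rng.randrange(i)
                edges.append((terms[i], terms[parent],
                              rng.choice(["is_a", "part_of"])))
                if rng.random() < 0.25 and i > 1:
                    second = rng.randrange(i)
                    if second != parent:
                        edges.append((terms[i], terms[second], "part_of"))
            genes = [f"g{i}" for i in range(rng.randint(1, 6))]
            annotations = {gene: rng.sample(terms, rng.randint(1, 3))
                           for gene in genes}
            g = _ontology_graph(edges, genes, annotations)
            picked = set(rng.sample(genes, rng.randint(1, len(genes))))
            sub = annotation_subnetwork(g, picked, "biological_process")
            seeds = {t for gene in picked for t in annotations[gene]}
            expected_terms = bfs_ancestor_closure(edges, seeds)
            got_terms = {c.accession for c in sub.concepts() if c.cls == "GO"}
            assert got_terms == expected_terms
            # every included term reaches a seed term going downward
            # (equivalently: is in the upward closure of the seeds) — implied
            # by equality with the oracle; also check genes:
            assert ({c.accession for c in sub.concepts() if c.cls == "Gene"}
                    == picked)

    def test_removing_a_gene_never_adds_concepts(self):
        rng = random.Random(3)
        edges = [(f"T{i}", f"T{rng.randrange(i)}", "is_a") for i in range(1, 15)]
        genes = [f"g{i}" for i in range(4)]
        annotations = {gene: [f"T{rng.randrange(15)}"] for gene in genes}
        g = _ontology_graph(edges, genes, annotations)
        full = annotation_subnetwork(g, set(genes), "biological_process")
        fewer = annotation_subnetwork(g, set(genes[:-1]), "biological_process")
        full_accs = {(c.cls, c.accession) for c in full.concepts()}
        fewer_accs = {(c.cls, c.accession) for c in fewer.concepts()}
        assert fewer_accs <= full_accs


class TestCategorySummary:
    def _dag(self):
        # root R with depth-1 categories metabolism / transport
        edges = [("metabolism", "R", "is_a"), ("transport", "R", "is_a"),
                 ("secondary", "metabolism", "is_a")]
        annotations = {
            "g1": ["secondary"],            # metabolism via ancestor
            "g2": ["metabolism"],
            "g3": ["metabolism", "transport"],  # two categories
            "g4": ["transport"],
        }
        return _ontology_graph(edges, list(annotations), annotations)

    def test_counts_and_percentages(self):
        g = self._dag()
        sub = annotation_subnetwork(g, {"g1", "g2", "g3", "g4"},
                                    "biological_process")
        rows = category_summary(sub)
        by_name = {r.category: r for r in rows}
        assert by_name["name metabolism"].gene_count == 3
        assert by_name["name metabolism"].percentage == pytest.approx(75.0)
        assert by_name["name transport"].gene_count == 2
        assert by_name["name transport"].percentage == pytest.approx(50.0)
        # multi-membership means percentages may sum above 100
        assert sum(r.percentage for r in rows) > 100

    def test_sorted_by_count_then_name(self):
        g = self._dag()
        sub = annotation_subnetwork(g, {"g1", "g2", "g3", "g4"},
                                    "biological_process")
        rows = category_summary(sub)
        assert [r.category for r in rows] == ["name metabolism",
                                              "name transport"]

    def test_all_genes_one_category(self):
        edges = [("metabolism", "R", "is_a")]
        annotations = {"g1": ["metabolism"], "g2": ["metabolism"]}
        g = _ontology_graph(edges, list(annotations), annotations)
        sub = annotation_subnetwork(g, {"g1", "g2"}, "biological_process")
        rows = category_summary(sub)
        assert len(rows) == 1
        assert rows[0].percentage == pytest.approx(100.0)

    def test_category_map_override(self):
        g = self._dag()
        sub = annotation_subnetwork(g, {"g2", "g3"}, "biological_process")
        rows = category_summary(sub, category_map={"name metabolism": "M",
                                                   "name transport": "M"})
        assert len(rows) == 1 and rows[0].category == "M"
        assert rows[0].gene_count == 2


def union_find_components(n, edges):
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    return len({find(i) for i in range(n)})


class TestRankComponents:
    def test_sorted_by_size_then_accession(self):
        g = InformationGraph()
        # sizes 5, 3, 3
        ids = {}
        for i in range(5):
            ids[f"a{i}"] = g.add_concept("Gene", f"a{i}")
        for i in range(4):
            g.add_relation(ids[f"a{i}"], ids[f"a{i + 1}"], "neighbor_of")
        for prefix in ("m", "b"):
            for i in range(3):
                ids[f"{prefix}{i}"] = g.add_concept("Gene", f"{prefix}{i}")
            g.add_relation(ids[f"{prefix}0"], ids[f"{prefix}1"], "neighbor_of")
            g.add_relation(ids[f"{prefix}1"], ids[f"{prefix}2"], "neighbor_of")
        comps = rank_components(g)
        assert [c.n_concepts for c in comps] == [5, 3, 3]
        assert [c.min_accession for c in comps] == ["a0", "b0", "m0"]

    def test_empty_graph(self, empty_graph):
        assert rank_components(empty_graph) == []

    def test_component_count_matches_union_find(self):
        rng = random.Random(12)
        for _ in range(15):
            n = rng.randint(1, 30)
            g = InformationGraph()
            ids = [g.add_concept("Gene", f"g{i}") for i in range(n)]
            edges = []
            for _ in range(rng.randint(0, 40)):
                a, b = rng.randrange(n), rng.randrange(n)
                if a != b:
                    g.add_relation(ids[a], ids[b], "neighbor_of")
                    edges.append((a, b))
            assert len(rank_components(g)) == union_find_components(n, edges)
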