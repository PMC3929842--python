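"""Shared fixtures: small hand-built graphs and seeded synthetic bundles."""

from __future__ import annotations

from pathlib import Path

import pytest

from fungraph import fixtures as fx
from fungraph import io_formats
from fungraph.graph_core import InformationGraph


@pytest.fixture
def empty_graph():
    return InformationGraph()


@pytest.fixture
def small_graph():
    """3 genes, 2 GO terms, 2 annotated_to edges, 1 is_a edge."""
    g = InformationGraph()
    g1 = g.add_concept("Gene", "AN7909", names=["AN7909", "orsA"])
    g2 = g.add_concept("Gene", "AN7910")
    g3 = g.add_concept("Gene", "AN7911")
    t1 = g.add_concept("GO", "GO:0001", names=["metabolism"])
    t2 = g.add_concept("GO", "GO:0002", names=["secondary metabolism"])
    g.set_attribute(t1, "namespace", "biological_process")
    g.set_attribute(t2, "namespace", "biological_process")
    g.add_relation(g1, t2, "annotated_to")
    g.add_relation(g2, t1, "annotated_to")
    g.add_relation(t2, t1, "is_a")
    g.genes = (g1, g2, g3)  # convenience handles for tests
    g.terms = (t1, t2)
    return g


def _accessions_by_chromosome(accessions):
    by_chrom: dict[str, list[str]] = {}
    for acc in accessions:
        by_chrom.setdefault(f"chr{int(acc[2:4])}", []).append(acc)
    return by_chrom


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Seeded synthetic input bundle: genome, ontology, expression with one
    planted 6-gene cluster on chr2 (contrast A48), corpus, adapter tables."""
    tmp = tmp_path_factory.mktemp("bundle")
    seed = 7
    _, accessions = fx.generate_genome(seed, n_chromosomes=3,
                                       genes_per_chromosome=15,
                                       out_path=tmp / "genome.gff3")
    fx.generate_ontology(seed, n_terms=15, out_path=tmp / "ontology.obo")
    by_chrom = _accessions_by_chromosome(accessions)
    planted = [fx.PlantedCluster("chr2", 4, 6, 12.0)]
    fx.generate_expression(seed, by_chrom, planted_clusters=planted,
                           planted_contrast="A48",
                           sample_out=tmp / "samples.tsv",
                           stats_out=tmp / "expression.tsv")
    fx.generate_corpus(seed, accessions, n_documents=3,
                       out_dir=tmp / "corpus")
    _, _, _, adapter_truth = fx.generate_adapter_fixtures(
        seed, accessions, out_dir=tmp / "adapters")
    return {
        "dir": tmp,
        "seed": seed,
        "accessions": accessions,
        "by_chrom": by_chrom,
        "planted": planted,
        "planted_contrast": "A48",
        "adapter_truth": adapter_truth,
    }


@pytest.fixture(scope="session")
def built_graph(bundle):
    """Network assembled from the synthetic bundle (genes + ontology +
    expression attributes); session-scoped, so treat as read-only."""
    cfg = {
        "loci": "genome.gff3",
        "ontologies": [{"path": "ontology.obo", "cls": "GO"}],
        "expression": "expression.tsv",
    }
    return io_formats.build_network(cfg, base_dir=bundle["dir"])


@pytest.fixture
def fresh_graph(bundle):
    """Per-test mutable copy of the assembled network."""
    cfg = {
        "loci": "genome.gff3",
        "ontologies": [{"path": "ontology.obo", "cls": "GO"}],
        "expression": "expression.tsv",
    }
    return io_formats.build_network(cfg, base_dir=bundle["dir"])
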