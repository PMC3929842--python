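"""Readers and writers for the network's input formats, plus graph assembly.

Supported inputs: OBO 1.2 ontologies (GO / FunCat), GFF3 gene loci, and
tab-separated tables for term annotation, orthology, publication curation,
metabolic links and per-contrast expression statistics.  ``build_network``
assembles everything into one :class:`~fungraph.graph_core.InformationGraph`.

Coordinate convention: GFF3 is 1-based inclusive on disk; internally all
loci are 0-based half-open, so ``length == end - start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import networkx as nx
import obonet
import pandas as pd
import yaml

from .expression_stats import ExpressionRecord, annotate_expression
from .graph_core import InformationGraph

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "OboParseError",
    "CycleError",
    "RecordError",
    "CoordinateError",
    "SchemaError",
    "GeneLocus",
    "AnnotationRow",
    "TermRecord",
    "BuildReport",
    "read_obo",
    "read_gff3_genes",
    "read_annotation_table",
    "read_expression_table",
    "build_network",
    "export_graph",
    "write_gff3_genes",
]

HIERARCHY_RELS = ("is_a", "part_of")


class FormatError(Exception):
    """Base class for input-format errors."""


class OboParseError(FormatError):
    pass


class CycleError(FormatError):
    pass


class RecordError(FormatError):
    pass


class CoordinateError(FormatError):
    pass


class SchemaError(FormatError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    """A gene position, 0-based half-open."""

    accession: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"  # '+', '-' or '?'

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise CoordinateError(f"{self.accession}: empty chromosome")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.accession}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationRow:
    gene_accession: str
    term_accession: str
    namespace: str
    evidence: str = ""


@dataclass(frozen=True)
class TermRecord:
    accession: str
    name: str
    namespace: str


@dataclass
class BuildReport:
    """Counters from one network assembly run."""

    dropped_annotations: int = 0
    dropped_rows: int = 0
    files: list[str] = field(default_factory=list)


# --------------------------------------------------------------------- OBO
def read_obo(path, cls: str = "GO"):
    """Parse an OBO 1.2 ontology into term records and hierarchy edges.

    Obsolete terms are skipped.  Only ``is_a`` and ``part_of`` edges are
    kept (others are counted and logged); edge direction is child -> parent.
    Returns ``(terms, edges)`` with edges as (child, parent, rel_type).
    Raises :class:`CycleError` if the kept hierarchy is not a DAG.
    """
    try:
        g = obonet.read_obo(str(path))
    except Exception as exc:  # malformed stanza, bad tag, ...
        raise OboParseError(f"{path}: {exc}") from exc
    terms = []
    for term_id, data in g.nodes(data=True):
        terms.append(TermRecord(
            accession=term_id,
            name=data.get("name", term_id),
            namespace=data.get("namespace", cls),
        ))
    edges = []
    ignored = 0
    for child, parent, key in g.edges(keys=True):
        if key in HIERARCHY_RELS:
            edges.append((child, parent, key))
        else:
            ignored += 1
    if ignored:
        log.info("read_obo(%s): ignored %d non-hierarchy edges", path, ignored)
    dag = nx.DiGraph((c, p) for c, p, _ in edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise CycleError(f"{path}: hierarchy contains a cycle: {cycle}")
    return terms, edges


# -------------------------------------------------------------------- GFF3
def read_gff3_genes(path) -> list[GeneLocus]:
    """Read gene features from GFF3 into sorted 0-based half-open loci.

    Sorted by (chromosome, start, end, accession).  Features of other
    types are ignored.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    loci = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids or not ids[0]:
            raise RecordError(
                f"{path}: gene feature at {feat.seqid}:{feat.start} lacks ID")
        if feat.end < feat.start:
            raise CoordinateError(
                f"{path}: gene {ids[0]} has end {feat.end} < start {feat.start}")
        strand = feat.strand if feat.strand in ("+", "-") else "?"
        loci.append(GeneLocus(accession=ids[0], chromosome=feat.seqid,
                              start=feat.start - 1, end=feat.end,
                              strand=strand))
    loci.sort(key=lambda l: (l.chromosome, l.start, l.end, l.accession))
    return loci


def write_gff3_genes(loci, path) -> None:
    """Write loci back out as GFF3 gene features (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write("\t".join([
                l.chromosome, "fungraph", "gene", str(l.start + 1), str(l.end),
                ".", l.strand if l.strand in "+-" else ".", ".",
                f"ID={l.accession}",
            ]) + "\n")


# --------------------------------------------------------------------- TSV
def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_annotation_table(path, namespace: str):
    """Read a gene->term TSV (columns: gene, term, optional evidence).

    Empty-gene/term rows are dropped and counted; exact duplicates collapse.
    Returns ``(rows, n_dropped)``.
    """
    df = _read_tsv(path, ("gene", "term"))
    n0 = len(df)
    df = df[(df["gene"] != "") & (df["term"] != "")]
    dropped = n0 - len(df)
    evid = df["evidence"] if "evidence" in df.columns else pd.Series("", index=df.index)
    rows = []
    seen = set()
    for gene, term, ev in zip(df["gene"], df["term"], evid):
        key = (gene, term, ev)
        if key in seen:
            continue
        seen.add(key)
        rows.append(AnnotationRow(gene_accession=gene, term_accession=term,
                                  namespace=namespace, evidence=ev))
    return rows, dropped


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read per-contrast expression statistics.

    Columns: gene, contrast, fold_change, p_value, adj_p (adj_p may be
    empty; it can be computed downstream).  p-values are clamped into
    [1e-300, 1].
    """
    df = _read_tsv(path, ("gene", "contrast", "fold_change", "p_value"))
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            fold = float(row.fold_change)
            p = float(row.p_value)
            adj = getattr(row, "adj_p", "")
            adj_p = float(adj) if adj not in ("", None) else None
        except (TypeError, ValueError) as exc:
            raise RecordError(f"{path}: row {i}: non-numeric statistic") from exc
        try:
            records.append(ExpressionRecord(
                gene_accession=row.gene, contrast=row.contrast,
                fold_change=fold, p_value=p, adj_p=adj_p))
        except ValueError as exc:
            raise RecordError(f"{path}: row {i}: {exc}") from exc
    return records


# ------------------------------------------------------------------- build
def _load_config(config, base_dir):
    if isinstance(config, (str, Path)):
        base = Path(config).parent if base_dir is None else Path(base_dir)
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh), base
    return config, Path(base_dir) if base_dir is not None else Path(".")


def build_network(config, base_dir=None) -> InformationGraph:
    """Assemble the integration network from a config mapping (or YAML path).

    Config keys (all optional except ``loci``)::

        loci: genome.gff3
        ontologies: [{path: go.obo, cls: GO}]
        annotations: [{path: annot.tsv, namespace: biological_process,
                       term_class: GO}]
        orthologs: [{path: orth.tsv, target_class: GeneAfu}]
        publications: pubs.tsv      # gene, publication[, title, year]
        metabolic: metabolic.tsv    # gene, reaction[, metabolite]
        expression: expr.tsv        # gene, contrast, fold_change, p_value, adj_p

    Genes exist only through the loci file; annotations referencing unknown
    genes are dropped and counted in ``graph.build_report``.
    """
    config, base = _load_config(config, base_dir)
    graph = InformationGraph()
    report = BuildReport()

    def _p(rel):
        return str(base / rel)

    def _fail(path, exc):
        raise FormatError(f"while reading {path}: {exc}") from exc

    # genes from loci — the single source of gene existence
    loci_path = config.get("loci")
    gene_ids: dict[str, int] = {}
    if loci_path:
        try:
            loci = read_gff3_genes(_p(loci_path))
        except Exception as exc:
            _fail(loci_path, exc)
        report.files.append(str(loci_path))
        for l in loci:
            cid = graph.add_concept("Gene", l.accession, source="genome")
            graph.set_attribute(cid, "chromosome", l.chromosome)
            graph.set_attribute(cid, "start", l.start)
            graph.set_attribute(cid, "end", l.end)
            graph.set_attribute(cid, "strand", l.strand)
            gene_ids[l.accession] = cid

    # ontologies
    term_ids: dict[tuple[str, str], int] = {}
    for spec in config.get("ontologies", []):
        cls = spec.get("cls", "GO")
        try:
            terms, edges = read_obo(_p(spec["path"]), cls=cls)
        except Exception as exc:
            _fail(spec["path"], exc)
        report.files.append(str(spec["path"]))
        for t in terms:
            cid = graph.add_concept(cls, t.accession, names=[t.name],
                                    source="ontology")
            graph.set_attribute(cid, "namespace", t.namespace)
            term_ids[(cls, t.accession)] = cid
        for child, parent, rel in edges:
            graph.add_relation(term_ids[(cls, child)], term_ids[(cls, parent)],
                               rel, evidence=["ontology"])

    # gene -> term annotations
    for spec in config.get("annotations", []):
        term_cls = spec.get("term_class", "GO")
        try:
            rows, dropped = read_annotation_table(_p(spec["path"]),
                                                  spec.get("namespace", term_cls))
        except Exception as exc:
            _fail(spec["path"], exc)
        report.files.append(str(spec["path"]))
        report.dropped_rows += dropped
        for row in rows:
            gid = gene_ids.get(row.gene_accession)
            tid = term_ids.get((term_cls, row.term_accession))
            if gid is None or tid is None:
                report.dropped_annotations += 1
                continue
            graph.add_relation(gid, tid, "annotated_to",
                               evidence=[row.evidence] if row.evidence else None)

    # orthology: gene -> GeneAfu/GeneScer concepts
    for spec in config.get("orthologs", []):
        target_cls = spec.get("target_class", "GeneAfu")
        try:
            rows, dropped = read_annotation_table(_p(spec["path"]), "ortholog_of")
        except Exception as exc:
            _fail(spec["path"], exc)
        report.files.append(str(spec["path"]))
        report.dropped_rows += dropped
        for row in rows:
            gid = gene_ids.get(row.gene_accession)
            if gid is None:
                report.dropped_annotations += 1
                continue
            oid = graph.add_concept(target_cls, row.term_accession,
                                    source="orthology")
            graph.add_relation(gid, oid, "ortholog_of")

    # curated publications: publication -> gene "mentions"
    pubs_path = config.get("publications")
    if pubs_path:
        try:
            df = _read_tsv(_p(pubs_path), ("gene", "publication"))
        except Exception as exc:
            _fail(pubs_path, exc)
        report.files.append(str(pubs_path))
        for row in df.itertuples(index=False):
            if not row.gene or not row.publication:
                report.dropped_rows += 1
                continue
            gid = gene_ids.get(row.gene)
            if gid is None:
                report.dropped_annotations += 1
                continue
            title = getattr(row, "title", "")
            pid = graph.add_concept("Publication", row.publication,
                                    names=[title] if title else None,
                                    source="curation")
            year = getattr(row, "year", "")
            if year:
                graph.set_attribute(pid, "year", int(year))
            graph.add_relation(pid, gid, "mentions", evidence=["curation"])

    # metabolic model: gene regulates reaction; reaction involves metabolite
    metab_path = config.get("metabolic")
    if metab_path:
        try:
            df = _read_tsv(_p(metab_path), ("gene", "reaction"))
        except Exception as exc:
            _fail(metab_path, exc)
        report.files.append(str(metab_path))
        for row in df.itertuples(index=False):
            if not row.reaction:
                report.dropped_rows += 1
                continue
            rid = graph.add_concept("Reaction", row.reaction, source="metabolic")
            if row.gene:
                gid = gene_ids.get(row.gene)
                if gid is None:
                    report.dropped_annotations += 1
                else:
                    graph.add_relation(gid, rid, "regulates")
            metabolite = getattr(row, "metabolite", "")
            if metabolite:
                mid = graph.add_concept("Metabolite", metabolite,
                                        source="metabolic")
                graph.add_relation(rid, mid, "involves")

    # expression statistics as gene attributes
    expr_path = config.get("expression")
    if expr_path:
        try:
            records = read_expression_table(_p(expr_path))
        except Exception as exc:
            _fail(expr_path, exc)
        report.files.append(str(expr_path))
        for contrast in sorted({r.contrast for r in records}):
            annotate_expression(graph, records, contrast)

    legend = graph.meta_legend()
    log.info("build_network: %d concepts, %d relations; legend %s",
             legend.n_concepts, legend.n_relations, legend.concept_counts)
    graph.build_report = report  # type: ignore[attr-defined]
    return graph


def export_graph(graph: InformationGraph, path, fmt: str = "jsonl") -> None:
    if fmt == "jsonl":
        graph.to_jsonl(path)
    elif fmt == "graphml":
        graph.to_graphml(path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
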