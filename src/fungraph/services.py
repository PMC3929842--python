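"""Adapters for the on-the-fly integrations and their graph plumbing.

Three service contracts back the context-sensitive operations: sequence
retrieval (gene -> protein sequence), protein-domain prediction, and
pairwise similarity search with reciprocal-best-hit (RBH) confirmation.
The default backends are deterministic fixture tables (FASTA / TSV), so
every workflow runs offline and reproducibly; live HTTP backends can plug
into the same contracts but are never required.

All integrations are idempotent at the graph level: concepts dedup by
accession and relations by (source, target, type), so re-running an
operation adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .context_ops import register_operation
from .graph_core import InformationGraph

__all__ = [
    "ServiceError",
    "SimilarityHit",
    "DomainHit",
    "FastaSequenceAdapter",
    "TableDomainAdapter",
    "TableSimilarityAdapter",
    "fetch_sequences",
    "scan_domains",
    "homology_search",
    "rbh_confirm",
    "integrate_hits",
]


class ServiceError(Exception):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    query_accession: str
    hit_accession: str
    hit_description: str
    identity_percent: float  # 0..100
    e_value: float           # >= 0
    source_db: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.identity_percent <= 100:
            raise ValueError("identity_percent must lie in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass(frozen=True)
class DomainHit:
    protein_accession: str
    domain_accession: str
    description: str
    start: int  # residue positions, 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("need 1 <= start <= end")


_HIT_SORT = lambda h: (h.e_value, -h.identity_percent, h.hit_accession)


class FastaSequenceAdapter:
    """Gene -> (protein accession, sequence) lookup from a FASTA fixture.

    FASTA headers carry the protein accession as the record id and the
    encoding gene as a ``gene=...`` token in the description.
    """

    def __init__(self, fasta_path) -> None:
        self._by_gene: dict[str, tuple[str, str]] = {}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            gene = None
            for token in rec.description.split():
                if token.startswith("gene="):
                    gene = token[5:]
            key = gene if gene else rec.id
            self._by_gene[key] = (rec.id, str(rec.seq))

    def get_for_gene(self, gene_accession: str) -> tuple[str, str] | None:
        return self._by_gene.get(gene_accession)


class TableDomainAdapter:
    """Protein -> domain hits from a TSV fixture
    (columns: protein, domain, description, start, end)."""

    def __init__(self, tsv_path) -> None:
        self._df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str,
                               keep_default_na=False)

    def hits(self, protein_accession: str) -> list[DomainHit]:
        rows = self._df[self._df["protein"] == protein_accession]
        out = [DomainHit(protein_accession=r.protein, domain_accession=r.domain,
                         description=r.description, start=int(r.start),
                         end=int(r.end))
               for r in rows.itertuples(index=False)]
        out.sort(key=lambda h: (h.start, h.domain_accession))
        return out


class TableSimilarityAdapter:
    """Directed pairwise similarity table
    (columns: query, hit, identity, e_value[, db, description])."""

    def __init__(self, tsv_path) -> None:
        self._df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype=str,
                               keep_default_na=False)

    def search(self, query_accession: str) -> list[SimilarityHit]:
        rows = self._df[self._df["query"] == query_accession]
        out = [SimilarityHit(
            query_accession=r.query, hit_accession=r.hit,
            hit_description=getattr(r, "description", ""),
            identity_percent=float(r.identity), e_value=float(r.e_value),
            source_db=getattr(r, "db", ""))
            for r in rows.itertuples(index=False)]
        out.sort(key=_HIT_SORT)
        return out


# ----------------------------------------------------------------- plumbing
def fetch_sequences(graph: InformationGraph, adapter, gene_accessions):
    """Create Protein concepts (+ encodes relations) for resolvable genes.

    Returns ``(resolved, unresolved)``: a map gene accession ->
    (protein accession, sequence), and the list of accessions the adapter
    could not resolve.
    """
    resolved: dict[str, tuple[str, str]] = {}
    unresolved: list[str] = []
    for acc in gene_accessions:
        entry = adapter.get_for_gene(acc)
        if entry is None:
            unresolved.append(acc)
            continue
        prot_acc, seq = entry
        pid = graph.add_concept("Protein", prot_acc, source="sequence_service")
        graph.set_attribute(pid, "sequence.protein", seq)
        gid = graph.find("Gene", acc)
        if gid is None:
            gid = graph.add_concept("Gene", acc)
        graph.add_relation(gid, pid, "encodes", evidence=["sequence_service"])
        resolved[acc] = (prot_acc, seq)
    return resolved, unresolved


def scan_domains(graph: InformationGraph, adapter, protein_id: int
                 ) -> list[DomainHit]:
    """Predict domains for a protein concept and integrate the hits.

    One ProteinDomain concept per distinct domain accession; has_domain
    relations carry residue start/end.  Requires a sequence attribute.
    """
    protein = graph.concept(protein_id)
    if "sequence.protein" not in protein.attributes:
        raise ServiceError(f"protein {protein.accession} has no sequence")
    hits = adapter.hits(protein.accession)
    for h in hits:
        did = graph.add_concept("ProteinDomain", h.domain_accession,
                                names=[h.description] if h.description else None,
                                source="domain_service")
        graph.add_relation(protein_id, did, "has_domain",
                           attributes={"start": h.start, "end": h.end},
                           evidence=["domain_service"])
    return hits


def homology_search(adapter, query_accession: str, max_evalue: float = 1e-5,
                    min_identity: float = 0.0) -> list[SimilarityHit]:
    """Similarity hits for an accession, filtered and deterministically
    sorted by (e-value asc, identity desc, hit accession).  Both filter
    comparisons are inclusive."""
    hits = [h for h in adapter.search(query_accession)
            if h.e_value <= max_evalue and h.identity_percent >= min_identity]
    hits.sort(key=_HIT_SORT)
    return hits


def rbh_confirm(adapter, query_accession: str, hit: SimilarityHit) -> bool:
    """Reciprocal-best-hit check: query and hit must each rank the other
    first under (e-value asc, identity desc, accession).  An empty search
    in either direction is unconfirmed, not an error."""
    forward = sorted(adapter.search(query_accession), key=_HIT_SORT)
    reverse = sorted(adapter.search(hit.hit_accession), key=_HIT_SORT)
    if not forward or not reverse:
        return False
    return (forward[0].hit_accession == hit.hit_accession
            and reverse[0].hit_accession == query_accession)


def integrate_hits(graph: InformationGraph, query_id: int, hits,
                   confirmed_only: bool = False, confirmed: set[str] | None = None,
                   hit_class: str = "Protein") -> tuple[int, int]:
    """Add hit concepts and similar_to relations for similarity hits.

    With ``confirmed_only`` only accessions in ``confirmed`` integrate.
    Returns (concepts_added, relations_added); zero on re-integration.
    """
    concepts_added = relations_added = 0
    for h in hits:
        if confirmed_only and (confirmed is None or h.hit_accession not in confirmed):
            continue
        existed = graph.find(hit_class, h.hit_accession) is not None
        cid = graph.add_concept(
            hit_class, h.hit_accession,
            names=[h.hit_description] if h.hit_description else None,
            source=h.source_db or "similarity_service")
        if not existed:
            concepts_added += 1
        if not graph.has_relation(query_id, cid, "similar_to"):
            relations_added += 1
        graph.add_relation(query_id, cid, "similar_to",
                           attributes={"identity_percent": h.identity_percent,
                                       "e_value": h.e_value},
                           evidence=["similarity_service"])
    return concepts_added, relations_added


# ----------------------------------------------- registered menu operations
@register_operation("fetch_sequences")
def _op_fetch_sequences(graph, selection_ids, params, context):
    adapter = context.get("sequences")
    if adapter is None:
        raise ServiceError("no sequence adapter configured")
    genes = [graph.concept(cid).accession for cid in selection_ids
             if graph.registry.is_a(graph.concept(cid).cls, "Gene")]
    resolved, unresolved = fetch_sequences(graph, adapter, genes)
    return f"resolved {len(resolved)} sequences ({len(unresolved)} unresolved)"


@register_operation("predict_domains")
def _op_predict_domains(graph, selection_ids, params, context):
    adapter = context.get("domains")
    if adapter is None:
        raise ServiceError("no domain adapter configured")
    n = 0
    for cid in selection_ids:
        if graph.concept(cid).cls == "Protein":
            n += len(scan_domains(graph, adapter, cid))
    return f"{n} domain hits integrated"


@register_operation("blast_homology")
def _op_blast_homology(graph, selection_ids, params, context):
    adapter = context.get("similarity")
    if adapter is None:
        raise ServiceError("no similarity adapter configured")
    max_evalue = float(params.get("max_evalue", 1e-5))
    min_identity = float(params.get("min_identity", 0.0))
    bidirectional = str(params.get("bidirectional", "true")).lower() != "false"
    total_c = total_r = 0
    for cid in selection_ids:
        concept = graph.concept(cid)
        if concept.cls != "Protein":
            continue
        hits = homology_search(adapter, concept.accession,
                               max_evalue=max_evalue, min_identity=min_identity)
        confirmed = {h.hit_accession for h in hits
                     if rbh_confirm(adapter, concept.accession, h)}
        c, r = integrate_hits(graph, cid, hits,
                              confirmed_only=bidirectional, confirmed=confirmed)
        total_c += c
        total_r += r
    return f"integrated {total_c} concepts / {total_r} relations"
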