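"""Chromosomal adjacency and differentially-expressed gene-cluster detection.

Fungal secondary-metabolite pathways tend to be encoded by chromosomally
adjacent genes, so runs of neighbouring strongly differentially expressed
genes are candidate biosynthetic clusters.  This module chains consecutive
genes per chromosome with ``neighbor_of`` edges, computes a per-chromosome
track layout, and detects maximal runs of DE genes with a bounded number of
interior non-DE gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .graph_core import InformationGraph

__all__ = [
    "ClusterCall",
    "build_neighbor_edges",
    "genomic_layout",
    "find_de_runs",
    "detect_de_clusters",
]


@dataclass
class ClusterCall:
    """One detected run of neighbouring DE genes (span may include gaps)."""

    chromosome: str
    first_gene: str
    last_gene: str
    gene_accessions: list[str]  # every locus in the span, chromosomal order
    n_de: int                   # members passing the DE filter
    contrast: str


def _genes_with_loci(graph: InformationGraph):
    """(concept, chromosome, start, end) for genes with locus attributes;
    genes without a locus are skipped with a warning."""
    out, skipped = [], 0
    for c in graph.concepts_of_class("Gene"):
        chrom = c.attributes.get("chromosome")
        start = c.attributes.get("start")
        end = c.attributes.get("end")
        if chrom is None or start is None or end is None:
            skipped += 1
            continue
        out.append((c, str(chrom), int(start), int(end)))
    if skipped:
        warnings.warn(f"{skipped} gene concepts lack locus attributes",
                      stacklevel=3)
    return out


def _by_chromosome(graph: InformationGraph) -> dict[str, list]:
    chroms: dict[str, list] = {}
    for c, chrom, start, end in _genes_with_loci(graph):
        chroms.setdefault(chrom, []).append((start, end, c.accession, c))
    for genes in chroms.values():
        genes.sort(key=lambda t: (t[0], t[1], t[2]))
    return chroms


def build_neighbor_edges(graph: InformationGraph) -> int:
    """Link each pair of consecutive genes per chromosome with neighbor_of.

    Order within a chromosome is (start, end, accession).  Returns the
    number of edges added; for chromosome gene counts n_c the total over a
    fresh graph is sum(n_c - 1).
    """
    added = 0
    chroms = _by_chromosome(graph)
    for chrom in sorted(chroms):
        genes = chroms[chrom]
        for (_, _, _, a), (_, _, _, b) in zip(genes, genes[1:]):
            if not graph.has_relation(a.id, b.id, "neighbor_of"):
                added += 1
            graph.add_relation(a.id, b.id, "neighbor_of",
                               evidence=["genomic_position"])
    return added


def genomic_layout(graph: InformationGraph, x_scale: float = 1.0,
                   track_spacing: float = 1.0) -> dict[int, tuple[float, float]]:
    """Per-chromosome track coordinates: one horizontal track (y) per
    chromosome, x proportional to gene start."""
    coords: dict[int, tuple[float, float]] = {}
    chroms = _by_chromosome(graph)
    for track, chrom in enumerate(sorted(chroms)):
        y = track * track_spacing
        for start, _end, _acc, concept in chroms[chrom]:
            coords[concept.id] = (start * x_scale, y)
    return coords


def find_de_runs(flags, min_run: int, max_gap: int) -> list[tuple[int, int, int]]:
    """Maximal runs of True flags allowing bounded interior gaps.

    A run is a window [i, j] (inclusive indices into ``flags``) that starts
    and ends with a flagged position, contains no streak of more than
    ``max_gap`` consecutive unflagged positions, and holds at least
    ``min_run`` flagged positions.  Reported runs are maximal and disjoint.
    Returns (i, j, n_flagged) tuples in position order.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ones = [i for i, f in enumerate(flags) if f]
    runs: list[tuple[int, int, int]] = []
    k = 0
    while k < len(ones):
        start = k
        while (k + 1 < len(ones)
               and ones[k + 1] - ones[k] - 1 <= max_gap):
            k += 1
        n_de = k - start + 1
        if n_de >= min_run:
            runs.append((ones[start], ones[k], n_de))
        k += 1
    return runs


def detect_de_clusters(graph: InformationGraph, contrast: str,
                       min_fold: float = 8.0, max_adjp: float = 0.05,
                       min_run: int = 3, max_gap: int = 1) -> list[ClusterCall]:
    """Detect runs of neighbouring DE genes per chromosome.

    A gene is flagged DE iff its ``fold_change.<contrast>`` /
    ``adj_p.<contrast>`` attributes pass |fold| >= min_fold and
    adj_p <= max_adjp (inclusive).  Runs must start and end with a DE gene
    and may contain at most ``max_gap`` consecutive non-DE genes inside.
    Results are sorted by (chromosome, span start).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    fold_key = f"fold_change.{contrast}"
    adjp_key = f"adj_p.{contrast}"
    calls: list[ClusterCall] = []
    chroms = _by_chromosome(graph)
    for chrom in sorted(chroms):
        genes = chroms[chrom]
        flags = []
        for _start, _end, _acc, c in genes:
            fold = c.attributes.get(fold_key)
            adjp = c.attributes.get(adjp_key)
            flags.append(fold is not None and adjp is not None
                         and abs(float(fold)) >= min_fold
                         and float(adjp) <= max_adjp)
        for i, j, n_de in find_de_runs(flags, min_run, max_gap):
            span = [genes[k][2] for k in range(i, j + 1)]
            calls.append(ClusterCall(
                chromosome=chrom, first_gene=span[0], last_gene=span[-1],
                gene_accessions=span, n_de=n_de, contrast=contrast))
    return calls
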