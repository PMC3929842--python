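"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the study conditions of a fungal mutant-vs-wild-type
transcriptome experiment on a clustered genome: a multi-chromosome GFF3
genome with non-overlapping genes, a rooted ontology DAG, per-contrast
expression statistics with planted strongly differentially expressed gene
clusters on a quiet background, a literature corpus with gene names planted
at recorded offsets, and adapter fixture tables (protein FASTA, domain
table, pairwise similarity table with planted mutual-best and one-way
pairs).

Determinism: a single integer seed drives one named PRNG stream per
generator (``numpy`` SeedSequence spawn keyed by a generator-specific
constant), so identical calls are byte-identical and adding a generator
never perturbs the others.

The reference experimental design is four developmental stages (contrast
labels V14, V20, A48, S48), each measured with two biological replicates
of four technical replicates: 4 x 2 x 4 = 32 samples.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PAPER_DESIGN",
    "CONTRAST_LABELS",
    "PlantedCluster",
    "generate_genome",
    "generate_ontology",
    "generate_expression",
    "generate_corpus",
    "generate_adapter_fixtures",
]

# stages x biological replicates x technical replicates (per genotype)
PAPER_DESIGN = (4, 2, 4)
CONTRAST_LABELS = ("V14", "V20", "A48", "S48")

# fixed stream keys so generators have independent, stable PRNG streams
_STREAMS = {"genome": 11, "ontology": 23, "expression": 37, "corpus": 53,
            "adapters": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class PlantedCluster:
    """A run of consecutive strong DEGs planted on one chromosome."""

    chromosome: str
    first_rank: int  # 0-based rank of the first member in chromosome order
    length: int
    fold: float      # planted |fold-change| (>= the strong threshold)


# ------------------------------------------------------------------ genome
def generate_genome(seed: int, n_chromosomes: int = 3,
                    genes_per_chromosome: int = 5,
                    gene_length_range: tuple[int, int] = (500, 2000),
                    gap_range: tuple[int, int] = (100, 1000),
                    out_path=None) -> tuple[str, list[str]]:
    """Write a GFF3 genome of non-overlapping genes in coordinate order.

    Gene accessions are ``AN<chrom><index>`` style (digits guarantee they
    never collide with the all-letter corpus filler).  Returns
    ``(gff3_text, accessions)``; the text is also written to ``out_path``
    when given.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one gene")
    lo, hi = gene_length_range
    glo, ghi = gap_range
    if not (0 < lo <= hi) or not (0 < glo <= ghi):
        raise ValueError("length/gap ranges must be positive and ordered")
    rng = _rng(seed, "genome")
    lines = ["##gff-version 3"]
    accessions = []
    for ci in range(1, n_chromosomes + 1):
        chrom = f"chr{ci}"
        pos = 1
        for gi in range(1, genes_per_chromosome + 1):
            gap = int(rng.integers(glo, ghi + 1))
            length = int(rng.integers(lo, hi + 1))
            start = pos + gap          # 1-based inclusive
            end = start + length - 1
            pos = end + 1
            acc = f"AN{ci:02d}{gi:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            lines.append("\t".join([chrom, "fungraph_sim", "gene", str(start),
                                    str(end), ".", strand, ".", f"ID={acc}"]))
            accessions.append(acc)
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text, accessions


# ---------------------------------------------------------------- ontology
def generate_ontology(seed: int, n_terms: int = 15, max_children: int = 4,
                      namespace: str = "biological_process",
                      second_parent_fraction: float = 0.2,
                      out_path=None) -> str:
    """Write a rooted ontology DAG as valid OBO 1.2.

    Term 1 is the root; every later term gets one ``is_a`` parent among the
    earlier terms (bounded fan-out) and a fraction gets a second
    ``part_of`` parent, producing a DAG rather than a tree.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = _rng(seed, "ontology")
    parents: dict[int, list[tuple[int, str]]] = {1: []}
    n_children = {1: 0}
    for t in range(2, n_terms + 1):
        candidates = [u for u in range(1, t) if n_children[u] < max_children]
        if not candidates:
            candidates = list(range(1, t))
        parent = int(rng.choice(candidates))
        parents[t] = [(parent, "is_a")]
        n_children[parent] = n_children.get(parent, 0) + 1
        n_children[t] = 0
        others = [u for u in range(1, t) if u != parent]
        if others and rng.random() < second_parent_fraction:
            parents[t].append((int(rng.choice(others)), "part_of"))
    lines = ["format-version: 1.2", "ontology: synthetic",
             f"default-namespace: {namespace}", ""]
    for t in range(1, n_terms + 1):
        lines += [f"[Term]", f"id: SYN:{t:07d}", f"name: synthetic term {t}",
                  f"namespace: {namespace}"]
        for parent, rel in parents[t]:
            if rel == "is_a":
                lines.append(f"is_a: SYN:{parent:07d}")
            else:
                lines.append(f"relationship: part_of SYN:{parent:07d}")
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text


# -------------------------------------------------------------- expression
def generate_expression(seed: int, genome_accessions: dict[str, list[str]],
                        design: tuple[int, int, int] = PAPER_DESIGN,
                        planted_clusters: list[PlantedCluster] | None = None,
                        planted_contrast: str = "A48",
                        background_fold_sd: float = 0.2,
                        contrasts: tuple[str, ...] = CONTRAST_LABELS,
                        sample_out=None, stats_out=None):
    """Per-sample intensity matrix + per-contrast statistics with planted DEGs.

    ``genome_accessions`` maps chromosome -> ordered gene accessions.
    Planted genes get the planted signed |fold| with adj_p <= 1e-4 in
    ``planted_contrast``; background folds are drawn near 1 (lognormal,
    ``background_fold_sd``) with adj_p uniform on (0.05, 1], so at the
    strong thresholds the background set is empty by construction.

    Returns ``(sample_tsv, stats_tsv)`` texts; the sample table has
    stages x bio x tech sample columns.
    """
    planted_clusters = planted_clusters or []
    if planted_contrast not in contrasts:
        raise ValueError(f"planted contrast {planted_contrast!r} not in contrasts")
    n_stages, n_bio, n_tech = design
    if len(contrasts) != n_stages:
        raise ValueError("need one contrast label per stage")
    rng = _rng(seed, "expression")

    planted: dict[str, float] = {}
    claimed: dict[str, set[int]] = {}
    for pc in planted_clusters:
        genes = genome_accessions.get(pc.chromosome)
        if genes is None or pc.first_rank + pc.length > len(genes):
            raise ValueError(f"planted cluster does not fit on {pc.chromosome}")
        ranks = set(range(pc.first_rank, pc.first_rank + pc.length))
        if claimed.get(pc.chromosome, set()) & ranks:
            raise ValueError(f"overlapping planted clusters on {pc.chromosome}")
        claimed.setdefault(pc.chromosome, set()).update(ranks)
        for r in sorted(ranks):
            sign = 1.0 if rng.random() < 0.7 else -1.0
            planted[genes[r]] = sign * pc.fold

    all_genes = [acc for chrom in sorted(genome_accessions)
                 for acc in genome_accessions[chrom]]

    # per-contrast statistics table
    stats_lines = ["gene\tcontrast\tfold_change\tp_value\tadj_p"]
    for contrast in contrasts:
        for acc in all_genes:
            if contrast == planted_contrast and acc in planted:
                fold = planted[acc]
                adj_p = float(rng.uniform(1e-8, 1e-4))
                p = adj_p / 2
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                fold = sign * float(np.exp(abs(rng.normal(0.0, background_fold_sd))))
                adj_p = float(rng.uniform(0.05, 1.0))
                p = adj_p * float(rng.uniform(0.2, 1.0))
            stats_lines.append(f"{acc}\t{contrast}\t{fold:.6g}\t{p:.6g}\t{adj_p:.6g}")
    stats_tsv = "\n".join(stats_lines) + "\n"

    # sample-level matrix: one column per stage x bio x tech
    columns = [f"{contrasts[s]}_b{b + 1}_t{t + 1}"
               for s in range(n_stages) for b in range(n_bio) for t in range(n_tech)]
    sample_lines = ["gene\t" + "\t".join(columns)]
    base = rng.normal(8.0, 1.0, size=len(all_genes))
    for gi, acc in enumerate(all_genes):
        effect = np.log2(abs(planted[acc])) if acc in planted else 0.0
        row = []
        for s in range(n_stages):
            on = contrasts[s] == planted_contrast and acc in planted
            for _b in range(n_bio):
                for _t in range(n_tech):
                    val = base[gi] + (effect if on else 0.0) + rng.normal(0.0, 0.25)
                    row.append(f"{val:.4f}")
        sample_lines.append(acc + "\t" + "\t".join(row))
    sample_tsv = "\n".join(sample_lines) + "\n"

    if sample_out is not None:
        Path(sample_out).write_text(sample_tsv, encoding="utf-8")
    if stats_out is not None:
        Path(stats_out).write_text(stats_tsv, encoding="utf-8")
    return sample_tsv, stats_tsv


# ------------------------------------------------------------------ corpus
_FILLER_WORDS = (
    "mycelium spore hyphae culture growth medium strain colony biosynthesis "
    "metabolite pathway regulation development conidia sexual asexual "
    "transcript expression analysis experiment laboratory condition induce "
    "silent secondary product enzyme synthase cluster fungal species"
).split()


def generate_corpus(seed: int, gene_accessions, n_documents: int = 3,
                    mentions_per_doc: int = 4, out_dir=None):
    """Documents of filler prose with gene names planted at known offsets.

    Filler words are all-letter tokens while gene accessions contain
    digits, so no accidental (case-insensitive, word-bounded) match can
    occur; every hit a scanner reports must be planted.  Returns
    ``(documents, truth)`` where truth is a list of (doc_id, gene, offset)
    and documents maps doc_id -> (title, year, text).
    """
    gene_accessions = list(gene_accessions)
    if n_documents < 0:
        raise ValueError("n_documents must be >= 0")
    if n_documents and not gene_accessions:
        raise ValueError("need at least one gene accession")
    rng = _rng(seed, "corpus")
    documents: dict[str, tuple[str, int, str]] = {}
    truth: list[tuple[str, str, int]] = []
    for di in range(1, n_documents + 1):
        doc_id = f"PMC{900000 + di}"
        words = []
        mention_at = set(rng.choice(np.arange(5, 5 + 10 * mentions_per_doc),
                                    size=mentions_per_doc, replace=False))
        n_words = 5 + 10 * mentions_per_doc + 5
        for wi in range(n_words):
            if wi in mention_at:
                words.append(str(rng.choice(gene_accessions)))
            else:
                words.append(str(rng.choice(_FILLER_WORDS)))
        text = " ".join(words) + "."
        offset = 0
        for wi, word in enumerate(words):
            if wi in mention_at:
                truth.append((doc_id, word, offset))
            offset += len(word) + 1
        year = int(2005 + rng.integers(0, 10))
        title = f"synthetic study {di}"
        documents[doc_id] = (title, year, text)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = ["id\ttitle\tyear"]
        for doc_id in sorted(documents):
            title, year, text = documents[doc_id]
            (out / f"{doc_id}.txt").write_text(text, encoding="utf-8")
            meta.append(f"{doc_id}\t{title}\t{year}")
        (out / "metadata.tsv").write_text("\n".join(meta) + "\n", encoding="utf-8")
        truth_lines = ["document\tgene\toffset"]
        truth_lines += [f"{d}\t{g}\t{o}" for d, g, o in truth]
        (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n",
                                       encoding="utf-8")
    return documents, truth


# ---------------------------------------------------------------- adapters
def generate_adapter_fixtures(seed: int, gene_accessions,
                              domain_fraction: float = 0.5,
                              n_mutual_pairs: int = 2, n_oneway_pairs: int = 2,
                              seq_length: int = 120, out_dir=None):
    """Protein FASTA + domain TSV + pairwise similarity TSV fixtures.

    Every gene gets a protein (accession ``P_<gene>``) with a random amino
    acid sequence; a fraction get a domain; the similarity table plants
    ``n_mutual_pairs`` reciprocal-best pairs and ``n_oneway_pairs``
    one-way-best pairs against external accessions, so RBH confirmation has
    known ground truth.  Returns ``(fasta, domains_tsv, hits_tsv, truth)``
    with truth = {"mutual": [(query, hit)], "oneway": [(query, hit)]}.
    """
    gene_accessions = list(gene_accessions)
    if len(gene_accessions) < n_mutual_pairs + n_oneway_pairs:
        raise ValueError("not enough genes for the requested planted pairs")
    rng = _rng(seed, "adapters")
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    fasta_lines = []
    for acc in gene_accessions:
        seq = "".join(rng.choice(aa, size=seq_length))
        fasta_lines.append(f">P_{acc} gene={acc}")
        fasta_lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    fasta = "\n".join(fasta_lines) + "\n"

    domain_pool = [
        ("IPR029058", "alpha/beta hydrolase fold (serine hydrolase)"),
        ("IPR000073", "alpha/beta hydrolase fold-1"),
        ("IPR011701", "major facilitator superfamily transporter"),
        ("IPR014030", "polyketide synthase, ketosynthase domain"),
        ("IPR010071", "non-ribosomal peptide synthetase module"),
    ]
    n_dom = max(1, int(round(domain_fraction * len(gene_accessions))))
    with_domains = sorted(rng.choice(gene_accessions, size=n_dom, replace=False))
    dom_lines = ["protein\tdomain\tdescription\tstart\tend"]
    for acc in with_domains:
        dom_acc, desc = domain_pool[int(rng.integers(0, len(domain_pool)))]
        start = int(rng.integers(1, 30))
        end = start + int(rng.integers(40, seq_length - 35))
        dom_lines.append(f"P_{acc}\t{dom_acc}\t{desc}\t{start}\t{min(end, seq_length)}")
    domains_tsv = "\n".join(dom_lines) + "\n"

    chosen = list(rng.choice(gene_accessions,
                             size=n_mutual_pairs + n_oneway_pairs, replace=False))
    hit_lines = ["query\thit\tidentity\te_value\tdb\tdescription"]
    truth = {"mutual": [], "oneway": []}
    for i in range(n_mutual_pairs):
        q = f"P_{chosen[i]}"
        h = f"EXTM{i + 1:03d}"
        ident = float(rng.uniform(60, 95))
        ev = float(rng.uniform(1e-50, 1e-20))
        hit_lines.append(f"{q}\t{h}\t{ident:.1f}\t{ev:.3g}\tuniprot\tmutual best hit")
        hit_lines.append(f"{h}\t{q}\t{ident:.1f}\t{ev:.3g}\tuniprot\tmutual best hit")
        # a weaker decoy in each direction keeps the ranking non-trivial
        hit_lines.append(f"{q}\tEXTD{i + 1:03d}\t{ident - 20:.1f}\t{ev * 1e6:.3g}\tuniprot\tdecoy")
        truth["mutual"].append((q, h))
    for i in range(n_oneway_pairs):
        q = f"P_{chosen[n_mutual_pairs + i]}"
        h = f"EXTO{i + 1:03d}"
        ident = float(rng.uniform(55, 90))
        ev = float(rng.uniform(1e-40, 1e-15))
        hit_lines.append(f"{q}\t{h}\t{ident:.1f}\t{ev:.3g}\tuniprot\tone-way best hit")
        # the reverse search prefers a different sequence, breaking reciprocity
        hit_lines.append(f"{h}\tEXTZ{i + 1:03d}\t{ident + 4:.1f}\t{ev / 1e4:.3g}\tuniprot\treverse best")
        hit_lines.append(f"{h}\t{q}\t{ident - 5:.1f}\t{ev * 10:.3g}\tuniprot\treverse runner-up")
        truth["oneway"].append((q, h))
    hits_tsv = "\n".join(hit_lines) + "\n"

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "proteins.fasta").write_text(fasta, encoding="utf-8")
        (out / "domains.tsv").write_text(domains_tsv, encoding="utf-8")
        (out / "similarity.tsv").write_text(hits_tsv, encoding="utf-8")
    return fasta, domains_tsv, hits_tsv, truth
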