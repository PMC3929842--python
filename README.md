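# fungraph

Heterogeneous biological information networks with context-sensitive
subgraph workflows, built for exploratory analysis of fungal transcriptome
experiments.

## The problem

Prior knowledge for filamentous fungi such as *Aspergillus nidulans* is
scattered across ontologies, genome annotation, orthology mappings, curated
literature and metabolic models. Interpreting a differential-expression
experiment against that background — and especially hunting for
*secondary-metabolite gene clusters*, runs of chromosomally adjacent genes
that are jointly induced — requires all of it in one navigable structure.
`fungraph` assembles these sources into a typed property graph
("information network"): nodes are **concepts** (Gene, GO, FunCat, Pathway,
Publication, Metabolite, Reaction, Protein, ProteinDomain, plus orthologous
GeneAfu/GeneScer), edges are **relations** (`annotated_to`, `is_a`,
`part_of`, `neighbor_of`, `ortholog_of`, `mentions`, `encodes`,
`has_domain`, `similar_to`, …), and every element carries accessions,
synonyms, attributes and data-source provenance.

On top of the network the package provides:

- **Expression statistics.** Per-contrast records (signed linear
  fold-change *FC*, raw *p*, Benjamini–Hochberg adjusted *p*). Replicate
  *p*-values combine by Stouffer's unweighted z-transformation,
  *z* = Σᵢ sᵢ·Φ⁻¹(1 − pᵢ/2) / √k, with two-sided combined
  *p* = 2(1 − Φ(|z|)). Genes filter as DEGs with the inclusive thresholds
  |FC| ≥ 4 ∧ p_adj ≤ 0.05, or *strong* DEGs at |FC| ≥ 8.
- **Genomic view.** Consecutive genes per chromosome are chained with
  `neighbor_of` edges and laid out on per-chromosome tracks; maximal runs of
  ≥ `min_run` strong DEGs with at most `max_gap` interior non-DE genes are
  reported as candidate biosynthetic clusters.
- **Annotation subnetworks.** For a gene set, the ontology terms annotated
  to it plus their full is_a/part_of ancestor closure, with top-level
  category summaries (a gene may count in several categories, so
  percentages can sum above 100).
- **Context-sensitive operations.** Declarative menu items (YAML or XML
  files in a nested directory) restrict registered operations — sequence
  retrieval, protein-domain prediction, reciprocal-best-hit (RBH) homology
  search, full-text literature scanning — to selections of particular
  concept classes. Operations run on a temporary induced subgraph and merge
  back only on success, so a failing operation leaves the main graph
  byte-identical.
- **Literature linking.** All gene names and synonyms become patterns of an
  Aho–Corasick automaton; documents are scanned case-insensitively with
  word boundaries and linked by `mentions` edges carrying occurrence
  counts.
- **Synthetic fixtures.** Seeded generators for every input (genome,
  ontology, expression with planted DEG clusters, corpus with planted
  mentions, adapter tables with planted mutual-best pairs) make the whole
  workflow runnable and testable offline.

## Worked example

```sh
fungraph fixtures make --seed 1 --out bundle
fungraph build --config bundle/config.yaml --out net.jsonl
fungraph filter-deg --expression bundle/expression.tsv --contrast A48 --strong
fungraph clusters --graph net.jsonl --contrast A48 --min-fold 8 --max-gap 0
```

prints

```
{"genes": 60, "out": "bundle"}
85 concepts, 29 relations
  GO	25
  Gene	60
AN02004
AN02005
AN02006
AN02007
AN02008
AN02009
chromosome	first_gene	last_gene	n_de	members
chr2	AN02004	AN02009	6	AN02004,AN02005,AN02006,AN02007,AN02008,AN02009
```

The bundle is a 3-chromosome synthetic genome (60 genes) with a 6-gene
strong-DEG cluster planted on chromosome 2 in contrast A48. The network
holds the 60 gene concepts plus a 25-term ontology; the strong filter
(|FC| ≥ 8, p_adj ≤ 0.05) returns exactly the six planted genes, and the
cluster detector reports them as one maximal run `AN02004–AN02009` — the
same read-out that flags real biosynthetic clusters such as the six-gene
orsellinic-acid region when the method is applied to genuine fungal
transcriptome data.

The same menu-driven operations are available from the shell, e.g.

```sh
fungraph ops run --graph net.jsonl --menu-dir menus --item biomart \
    --select AN01001,AN01002 --sequences bundle/adapters/proteins.fasta
```

which fetches protein sequences for the selection on a temporary subgraph
and reports the merge (`+2 concepts, +2 relations`).

## Layout

```
src/fungraph/
  graph_core.py       typed concept/relation graph, subgraphs, merge-back
  io_formats.py       OBO / GFF3 / TSV readers, network assembly, export
  expression_stats.py Stouffer, Benjamini–Hochberg, DEG filters, glyphs
  genomic_view.py     neighbor chains, track layout, DE-run detection
  annotation_net.py   ontology closure subnetworks, category summaries
  context_ops.py      menu tree, class restrictions, dispatch + isolation
  services.py         sequence/domain/similarity adapters, RBH, integration
  litsearch.py        Aho–Corasick multi-pattern search, mentions edges
  fixtures.py         seeded synthetic-data generators
  cli.py              command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
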