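# Methods

## The information network

The core container is a typed directed property graph. A *concept* is a
node with a concept class (from a single-inheritance class registry seeded
with Gene, GO, FunCat, Pathway, Publication, Metabolite, Reaction, GeneAfu,
GeneScer, Protein, ProteinDomain), a primary accession, an ordered name
list (first entry preferred, the rest synonyms), free-form attributes
(strings, numbers, lists of numbers; richer payloads such as protein
sequences are stored as string attributes named by convention,
`sequence.protein`), and a list of data-source labels. A *relation* is a
typed directed edge with attributes and evidence.

Identity and dedup decisions:

- External concept identity is the pair **(class, primary accession)**;
  accessions are the cross-source join handles, so adding an existing pair
  upserts (names, attributes and evidence are unioned). Conflicting
  attribute values are kept under suffixed keys (`key.2`, `key.3`, …)
  rather than guessing a precedence.
- Internal ids are opaque sequential integers; merges always match by
  accession, never by id, which keeps repeated merges stable.
- Relations are unique per (source, target, type); parallel edges collapse
  with attribute union, so the meta-legend counts relation types rather
  than multi-edges.
- GeneAfu and GeneScer (orthologous genes of *A. fumigatus* /
  *S. cerevisiae*) are subclasses of Gene, so class-restricted operations
  written for genes also apply to them.

The *meta-legend* summarises the schema: concepts per class and relations
per (source class, type, target class) triple. Its totals equal the raw
concept/relation counts by construction, and the test suite audits this —
together with the absence of dangling endpoints and index staleness —
after every mutating operation.

Temporary subgraphs are deep copies induced from a selection (all and only
relations with both endpoints selected). `merge_into` maps each temp
concept onto the main graph by accession, unions payloads, remaps
relations, and reports (added, added, updated) counts; it is idempotent
and order-insensitive for disjoint temps. Inducing a subgraph and merging
it back unchanged is a no-op.

Serialization is JSON Lines (one object per concept/relation with an
explicit `kind` field) as the canonical round-trip format, plus GraphML
export for external viewers. List-valued attributes are JSON-encoded in
GraphML since the format only carries scalars.

## Input formats

- **OBO 1.2** via `obonet`. Obsolete terms are skipped; only `is_a` and
  `part_of` edges are imported (others counted and logged), direction
  child → parent; a cycle in the kept hierarchy is an error.
- **GFF3** via `gffutils` (in-memory database). Only `gene` features are
  read; 1-based inclusive coordinates convert to 0-based half-open at the
  boundary, so `length == end − start` and export reproduces the input
  bit-exactly. Loci sort by (chromosome, start, end, accession).
- **TSV** tables (tab-separated, header row, `#` comments, UTF-8) serve
  annotation, orthology, publication, metabolic and expression roles.
  Rows with empty keys are dropped and counted; exact duplicates collapse.
- `build_network` assembles everything. Genes exist only through the loci
  file: annotations referencing unknown genes are dropped and counted in
  the build report rather than auto-created, keeping the genome the single
  source of gene existence. Any reader error aborts naming the offending
  file.

## Expression statistics

Fold-changes are **signed linear** ratios (+20.25 = 20.25-fold up,
−3.25 = 3.25-fold down); thresholds compare |FC|. Linear was chosen
because observed cluster genes reach values like 20.25 that are
implausible on a log₂ scale; a `--fold-scale` style conversion can be
applied on input where a source provides log folds.

- **Stouffer combination** (replicates): zᵢ = sᵢ·Φ⁻¹(1 − pᵢ/2) from the
  two-sided pᵢ and the replicate's fold direction sᵢ; z = Σzᵢ/√k
  (unweighted — no replicate weights are defined for this design);
  combined p = 2(1 − Φ(|z|)). p-values are clamped to [1e-300, 1] before
  Φ⁻¹ to avoid infinities. Whether the original analyses combined
  one-sided or two-sided p is not documented anywhere we could rely on;
  signed two-sided is this package's documented default.
- **Benjamini–Hochberg**: classic step-up, q₍ᵢ₎ = p₍ᵢ₎·m/i on the
  ascending order statistics, cumulative minimum from the largest rank
  down, capped at 1, returned in input order. Applied per contrast, not
  pooled: the stages are modelled independently. The implementation is
  verified against both a brute-force transcription of the definition and
  `statsmodels.multipletests(method="fdr_bh")`.
- **DEG filters**: gene included iff |FC| ≥ min_fold **and**
  p_adj ≤ max_adjp, both inclusive (the thresholds are printed as ≥ and
  ≤). Defaults 4/0.05 (DEG) and 8/0.05 (strong DEG); strong ⊆ DEG holds by
  construction and is asserted on every fixture.
- **Glyph attributes** for visual scaling: size = base·log₂(|FC| + 1)
  (strictly increasing, symmetric in sign), colour up/down by sign.

## Genomic view and cluster detection

"Neighbor" means rank-adjacent by start coordinate on the same chromosome,
strand ignored — one chain per chromosome. Ties (identical starts) break
by (end, accession) so edge construction is deterministic. The layout
places each chromosome on its own horizontal track with x proportional to
the gene start.

Cluster detection is run/gap based with explicit parameters because the
visual read-out it operationalises has no published numeric criterion: a
gene is flagged DE under the chosen thresholds; a reported run starts and
ends with a DE gene, contains at most `max_gap` consecutive non-DE genes
inside, holds at least `min_run` DE genes, and is maximal (reported runs
cannot be extended or merged under the gap rule; maximal valid windows are
provably disjoint, so a greedy left-to-right scan over the flagged
positions is exact). Defaults `min_run=3, max_gap=1` capture both a
compact 6-gene run and an extended ~21-gene region while suppressing
isolated DE singletons. The detector is verified against an exhaustive
window enumerator on random flag vectors for all parameter combinations
min_run ∈ {2..5} × max_gap ∈ {0,1,2}.

No biological function is claimed for a detected run; the detector flags
chromosomal colocation of strong DEGs, nothing more.

## Annotation subnetworks

For a gene set and an ontology namespace the subnetwork contains the
genes, the terms directly annotated to them, and every ancestor of those
terms up to the root (closure over is_a/part_of, upward only — descendants
of included ancestors that annotate none of the genes are excluded). Only
`annotated_to` and hierarchy relations survive. Multi-level annotations
are preserved: a gene annotated at two hierarchy levels stays connected to
both terms. The closure equals a breadth-first ancestor walk by
construction and is tested against one on random DAGs.

Top-level categories are the direct children of the namespace root in the
subnetwork. A gene counts toward category C iff any of its annotation
terms is C or has C as an ancestor; each gene counts once per category but
may appear in several, so percentages (100·count/|gene set|) may sum above
100. A user-supplied term → category mapping can rename or merge
categories where a manually curated grouping is preferred. Components rank
by concept count (ties by smallest member accession).

## Context-sensitive operations

Menu items are declarative files — YAML or XML, one per item, keys `id`,
`label`, `applies_to`, `match`, `operation`, `params` — arranged in a
nested directory whose relative paths become the menu hierarchy. Items
reference operations registered in code; embedding executable script code
in the item files is deliberately out of scope. Loading is a sorted
filesystem walk, so tree order is deterministic across platforms.

Applicability: an item with empty `applies_to` always applies; otherwise a
selected concept matches if its class is, or descends from, a listed
class. For multi-selections the default rule is **all** concepts must
match (batch operations act uniformly on every selected concept);
`match: any` relaxes this per item.

Dispatch runs the operation either on a temporary induced subgraph
(default) with merge-back on success, or in "main" mode. In both modes a
raised exception yields `status=error` and leaves the main graph
byte-identical — in temp mode because the operation only ever saw the
copy, in main mode because the operation runs on a working copy whose
state is swapped in only on success. This isolation contract is stricter
than any documented predecessor behaviour and is asserted by serializing
the graph before and after failing dispatches.

## Service adapters

Sequence retrieval, domain prediction and similarity search are adapter
contracts with deterministic table/FASTA backends, so tests and the
acceptance script never touch a network; live HTTP backends can implement
the same contracts but are optional and disabled by default.

- Similarity hits filter by e_value ≤ max_evalue (default 1e-5) and
  identity ≥ min_identity (default 0, both inclusive — no published
  cutoffs exist for this workflow, so the defaults are documented rather
  than inferred) and sort by (e-value asc, identity desc, accession).
- **RBH confirmation** requires a full reciprocal best hit: the query's
  rank-1 hit must be the candidate *and* the candidate's rank-1 hit must
  be the query, with rank 1 defined by the sort order above. An empty
  search in either direction is "unconfirmed", not an error. The check is
  verified against a brute-force mutual-best computation on random score
  tables.
- Integration adds one concept per hit accession and `similar_to` /
  `has_domain` / `encodes` relations with the hit statistics as
  attributes; accession dedup makes every integration idempotent.

## Literature search

All gene names and synonyms of length ≥ `min_pattern_len` (default 3,
dropping shorter synonyms guards against spurious two-letter matches)
are lowercased into an Aho–Corasick automaton. The matcher contract is
"exact multi-pattern, all occurrences"; the automaton is an implementation
choice and is validated against a naive O(n·m) scanner on random inputs,
including overlapping and nested patterns. Hits are case-insensitive and
word-bounded (adjacent characters must not be alphanumeric). Both the
case-folding and the boundary rule are configurable switches, since the
behaviour of prior tools on these points is undocumented.

Linking creates one Publication concept per document with ≥ 1 hit and one
`mentions` edge per (publication, gene) pair, with an `n_occurrences`
attribute; re-linking the same corpus adds nothing. No NLP is attempted —
no tokenization models, no entity disambiguation, no PDF parsing.

## Synthetic data

Generators are deterministic functions of (seed, parameters): one
`numpy` SeedSequence stream per generator, keyed by a fixed per-generator
constant, so adding a generator never changes another's output.

- **Genome**: non-overlapping genes in coordinate order, gene lengths
  500–2000 bp and intergenic gaps 100–1000 bp by default (compact,
  fungal-like gene density); accessions contain digits.
- **Ontology**: rooted DAG, each non-root term one `is_a` parent among
  earlier terms plus a 20% chance of a second `part_of` parent.
- **Expression**: the reference design is 4 stages × 2 biological × 4
  technical replicates = 32 sample columns per genotype (the sample total
  is read per genotype, which is the reading consistent with four stages
  of two-by-four replication). Planted cluster genes get the planted
  |fold| with p_adj ≤ 1e-4; background genes draw |log FC| ~ |N(0, 0.2)|
  (so |FC| ≲ 2) with p_adj uniform on (0.05, 1] — by construction the
  strong-DEG background is empty, making planted-truth recovery exact
  rather than probabilistic.
- **Corpus**: filler text uses all-letter words while gene accessions
  contain digits, so no accidental word-bounded match is possible; every
  planted (document, gene, offset) triple is recorded in a truth table.
- **Adapter tables**: every gene receives a random protein sequence; a
  configurable subset receives domains; the similarity table plants
  mutual-best pairs (with weaker decoys so ranking is non-trivial) and
  one-way pairs whose reverse search prefers a different sequence.

What the generators do **not** emulate: probe-level microarray noise,
normalization artefacts, correlated expression within real clusters,
realistic ontology term-name text, or homology score distributions.
Passing tests therefore demonstrate the correctness of the graph
machinery, statistics, detectors and matchers under controlled truth —
not the biological error rates these methods would achieve on real
*A. nidulans* data.

## Problem sizes and numerical choices

The test suite and acceptance script run synthetic studies of 3–6
chromosomes × 15–60 genes, 15–40-term ontologies, 3–5 documents, and
oracle-equivalence sweeps of 1000 random vectors (BH), 500 flag vectors ×
12 parameter combinations (cluster detection), 1000 random
text/dictionary pairs (scanning) and 200 random score tables (RBH) —
sizes at which the brute-force oracles are exact and fast. Floating-point
comparisons in tests use absolute tolerances of 1e-12 where both routes
compute the same closed form. p-values clamp to [1e-300, 1]; BH caps at 1;
tie-breaks everywhere are lexicographic on accession after the primary
keys, so all outputs are deterministic.

## Known limitations

- No live database connectivity is exercised; the adapter contracts are
  the extension point.
- The category summary reflects the ontology's own top level; a curated
  functional grouping must be supplied as a mapping to reproduce any
  manually defined category scheme.
- Relation multiplicity is collapsed per (source, target, type); workflows
  needing true parallel edges would need a schema extension.
- The graph is held in memory; genome-scale networks with millions of
  relations are out of scope.
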