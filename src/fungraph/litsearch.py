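"""Full-text literature linking by exact multi-pattern gene-name search.

Every gene name and synonym in the network becomes a search pattern; large
document bodies are scanned for all occurrences at once with an
Aho–Corasick automaton (equivalent to — and tested against — a naive
sliding-window scanner).  Matching is case-insensitive and bounded by word
boundaries: the characters adjacent to a hit must not be alphanumeric, so
"stcA" never matches inside "stcAB".  Publications with at least one hit
become Publication concepts linked to each mentioned gene by a single
``mentions`` relation carrying the occurrence count.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .context_ops import register_operation
from .graph_core import InformationGraph

__all__ = [
    "AhoCorasick",
    "TermIndex",
    "MatchHit",
    "Document",
    "build_term_index",
    "scan_text",
    "link_publications",
    "load_corpus",
]

DEFAULT_MIN_PATTERN_LEN = 3


class AhoCorasick:
    """Multi-pattern exact matcher (goto/fail automaton over characters)."""

    def __init__(self, patterns) -> None:
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        self._fail: list[int] = [0]
        for pat in patterns:
            self._insert(pat)
        self._build_failure_links()

    def _insert(self, pattern: str) -> None:
        node = 0
        for ch in pattern:
            nxt = self._goto[node].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._out.append([])
                self._fail.append(0)
                self._goto[node][ch] = nxt
            node = nxt
        self._out[node].append(pattern)

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str):
        """Yield (start_offset, pattern) for every occurrence, in scan order."""
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for pat in self._out[node]:
                yield i - len(pat) + 1, pat


@dataclass
class TermIndex:
    """Prebuilt pattern -> gene-accession index with its matcher state."""

    patterns: dict[str, set[str]]   # lowercased pattern -> accessions
    automaton: AhoCorasick
    min_pattern_len: int
    n_dropped: int                  # synonyms shorter than the minimum


@dataclass(frozen=True)
class MatchHit:
    document_id: str
    pattern: str     # as indexed (lowercased)
    offset: int      # 0-based character position in the document
    gene_accession: str


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    title: str = ""
    year: int | None = None


def build_term_index(source, min_pattern_len: int = DEFAULT_MIN_PATTERN_LEN
                     ) -> TermIndex:
    """Index all gene names and synonyms for multi-pattern search.

    ``source`` is either an :class:`InformationGraph` (all Gene concepts'
    names, synonyms and accessions are indexed) or a mapping accession ->
    list of names.  Patterns are lowercased; those shorter than
    ``min_pattern_len`` are dropped and counted.  A synonym shared by two
    genes maps to both accessions.
    """
    entries: dict[str, list[str]] = {}
    if isinstance(source, InformationGraph):
        for c in source.concepts_of_class("Gene"):
            entries[c.accession] = list(dict.fromkeys([c.accession] + c.names))
    else:
        entries = {acc: list(names) for acc, names in source.items()}
    patterns: dict[str, set[str]] = {}
    dropped = 0
    for acc, names in entries.items():
        for name in names:
            if len(name) < min_pattern_len:
                dropped += 1
                continue
            patterns.setdefault(name.lower(), set()).add(acc)
    if not patterns:
        warnings.warn("term index is empty", stacklevel=2)
    return TermIndex(patterns=patterns,
                     automaton=AhoCorasick(sorted(patterns)),
                     min_pattern_len=min_pattern_len, n_dropped=dropped)


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def scan_text(index: TermIndex, document_id: str, text: str) -> list[MatchHit]:
    """All word-bounded, case-insensitive pattern occurrences in a text.

    Hits sort by (offset, pattern); one hit per (occurrence, gene) pair.
    """
    lowered = text.lower()
    hits: list[MatchHit] = []
    for start, pat in index.automaton.iter_matches(lowered):
        end = start + len(pat)
        if start > 0 and _is_word_char(text[start - 1]):
            continue
        if end < len(text) and _is_word_char(text[end]):
            continue
        for acc in sorted(index.patterns[pat]):
            hits.append(MatchHit(document_id=document_id, pattern=pat,
                                 offset=start, gene_accession=acc))
    hits.sort(key=lambda h: (h.offset, h.pattern, h.gene_accession))
    return hits


def load_corpus(directory) -> list[Document]:
    """Read a corpus directory: one ``<id>.txt`` per document plus a
    ``metadata.tsv`` sidecar (columns: id, title, year)."""
    base = Path(directory)
    meta: dict[str, tuple[str, int | None]] = {}
    meta_path = base / "metadata.tsv"
    if meta_path.exists():
        df = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            year = int(row.year) if getattr(row, "year", "") else None
            meta[row.id] = (getattr(row, "title", ""), year)
    docs = []
    for path in sorted(base.glob("*.txt")):
        doc_id = path.stem
        title, year = meta.get(doc_id, ("", None))
        docs.append(Document(doc_id=doc_id, text=path.read_text(encoding="utf-8"),
                             title=title, year=year))
    return docs


def link_publications(graph: InformationGraph, corpus,
                      index: TermIndex | None = None,
                      min_pattern_len: int = DEFAULT_MIN_PATTERN_LEN) -> int:
    """Scan a corpus and draw publication -> gene ``mentions`` edges.

    One Publication concept per document with at least one hit; one edge
    per (publication, gene) pair with an ``n_occurrences`` attribute.
    Returns the number of newly created edges (0 on re-linking).
    """
    if index is None:
        index = build_term_index(graph, min_pattern_len=min_pattern_len)
    edges_added = 0
    for doc in corpus:
        hits = scan_text(index, doc.doc_id, doc.text)
        if not hits:
            continue
        counts: dict[str, int] = {}
        for h in hits:
            counts[h.gene_accession] = counts.get(h.gene_accession, 0) + 1
        pid = graph.add_concept("Publication", doc.doc_id,
                                names=[doc.title] if doc.title else None,
                                source="fulltext_search")
        if doc.year is not None:
            graph.set_attribute(pid, "year", doc.year)
        for acc, n in sorted(counts.items()):
            gid = graph.find("Gene", acc)
            if gid is None:
                continue
            if not graph.has_relation(pid, gid, "mentions"):
                edges_added += 1
            graph.add_relation(pid, gid, "mentions",
                               evidence=["fulltext_search"])
            graph.get_relation(pid, gid, "mentions").attributes["n_occurrences"] = n
    return edges_added


@register_operation("pubmed_fulltext")
def _op_fulltext_search(graph, selection_ids, params, context):
    corpus = context.get("corpus")
    if corpus is None:
        raise RuntimeError("no literature corpus configured")
    min_len = int(params.get("min_pattern_len", DEFAULT_MIN_PATTERN_LEN))
    selected = {}
    for cid in selection_ids:
        c = graph.concept(cid)
        if graph.registry.is_a(c.cls, "Gene"):
            selected[c.accession] = list(dict.fromkeys([c.accession] + c.names))
    index = build_term_index(selected, min_pattern_len=min_len)
    added = link_publications(graph, corpus, index=index)
    return f"{added} publication links added"
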