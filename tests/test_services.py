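"""Service adapters: sequence retrieval, domain prediction, similarity
search with reciprocal-best-hit confirmation against a brute-force
mutual-best oracle."""

import random

import pytest

from fungraph import services
from fungraph.graph_core import InformationGraph
from fungraph.services import (DomainHit, FastaSequenceAdapter, ServiceError,
                               SimilarityHit, TableDomainAdapter,
                               TableSimilarityAdapter, fetch_sequences,
                               homology_search, integrate_hits, rbh_confirm,
                               scan_domains)

FASTA = """\
>P_g1 gene=g1
MKTAYIAKQR
>P_g2 gene=g2
MSILVTRPSP
>CADANIAG00003918 gene=AN7899.4
MSERINEHYDROLASE
"""


@pytest.fixture
def seq_adapter(tmp_path):
    p = tmp_path / "seqs.fasta"
    p.write_text(FASTA)
    return FastaSequenceAdapter(p)


class TestFetchSequences:
    def test_lookup_semantics(self, seq_adapter):
        g = InformationGraph()
        for acc in ("g1", "g2", "absent"):
            g.add_concept("Gene", acc)
        resolved, unresolved = fetch_sequences(g, seq_adapter,
                                               ["g1", "g2", "absent"])
        assert set(resolved) == {"g1", "g2"}
        assert unresolved == ["absent"]
        assert g.meta_legend().concept_counts["Protein"] == 2

    def test_repeated_fetch_upserts(self, seq_adapter):
        g = InformationGraph()
        g.add_concept("Gene", "g1")
        fetch_sequences(g, seq_adapter, ["g1"])
        fetch_sequences(g, seq_adapter, ["g1"])
        assert g.meta_legend().concept_counts["Protein"] == 1

    def test_encodes_relation_created(self, seq_adapter):
        g = InformationGraph()
        gid = g.add_concept("Gene", "AN7899.4")
        fetch_sequences(g, seq_adapter, ["AN7899.4"])
        pid = g.find("Protein", "CADANIAG00003918")
        assert pid is not None
        assert g.has_relation(gid, pid, "encodes")
        assert g.concept(pid).attributes["sequence.protein"] == "MSERINEHYDROLASE"


DOMAINS = """\
protein\tdomain\tdescription\tstart\tend
P_g1\tIPR029058\tserine hydrolase fold\t10\t90
P_shared\tIPR029058\tserine hydrolase fold\t5\t80
"""


class TestScanDomains:
    @pytest.fixture
    def dom_adapter(self, tmp_path):
        p = tmp_path / "domains.tsv"
        p.write_text(DOMAINS)
        return TableDomainAdapter(p)

    def _protein(self, g, acc):
        pid = g.add_concept("Protein", acc)
        g.set_attribute(pid, "sequence.protein", "M" * 100)
        return pid

    def test_single_domain_integrated(self, dom_adapter):
        g = InformationGraph()
        pid = self._protein(g, "P_g1")
        hits = scan_domains(g, dom_adapter, pid)
        assert hits == [DomainHit("P_g1", "IPR029058",
                                  "serine hydrolase fold", 10, 90)]
        did = g.find("ProteinDomain", "IPR029058")
        assert g.has_relation(pid, did, "has_domain")
        rel = g.get_relation(pid, did, "has_domain")
        assert (rel.attributes["start"], rel.attributes["end"]) == (10, 90)

    def test_absent_protein_no_mutation(self, dom_adapter):
        g = InformationGraph()
        pid = self._protein(g, "P_unknown")
        before = g.serialize()
        assert scan_domains(g, dom_adapter, pid) == []
        assert g.serialize() == before

    def test_shared_domain_single_concept(self, dom_adapter):
        g = InformationGraph()
        p1 = self._protein(g, "P_g1")
        p2 = self._protein(g, "P_shared")
        scan_domains(g, dom_adapter, p1)
        scan_domains(g, dom_adapter, p2)
        assert g.meta_legend().concept_counts["ProteinDomain"] == 1
        assert g.meta_legend().relation_counts[
            ("Protein", "has_domain", "ProteinDomain")] == 2

    def test_missing_sequence_rejected(self, dom_adapter):
        g = InformationGraph()
        pid = g.add_concept("Protein", "P_g1")
        with pytest.raises(ServiceError):
            scan_domains(g, dom_adapter, pid)


HITS = """\
query\thit\tidentity\te_value\tdb\tdescription
Q\tA\t60.0\t1e-30\tuniprot\texact threshold
Q\tB\t80.0\t1e-30\tuniprot\ttie on e-value
Q\tC\t95.0\t1e-10\tuniprot\tweaker e-value
Q\tD\t40.0\t1e-3\tuniprot\tinsignificant
"""


class TestHomologySearch:
    @pytest.fixture
    def sim_adapter(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(HITS)
        return TableSimilarityAdapter(p)

    def test_min_identity_inclusive(self, sim_adapter):
        hits = homology_search(sim_adapter, "Q", max_evalue=1e-5,
                               min_identity=60.0)
        assert {h.hit_accession for h in hits} == {"A", "B", "C"}

    def test_no_perfect_hit_empty(self, sim_adapter):
        assert homology_search(sim_adapter, "Q", min_identity=100.0) == []

    def test_tie_break_identity_then_accession(self, sim_adapter):
        hits = homology_search(sim_adapter, "Q", max_evalue=1e-5)
        assert [h.hit_accession for h in hits] == ["B", "A", "C"]


def _table_adapter_from_scores(tmp_path, scores):
    """scores: {(query, hit): (identity, e_value)} -> adapter"""
    lines = ["query\thit\tidentity\te_value\tdb\tdescription"]
    for (q, h), (ident, ev) in sorted(scores.items()):
        lines.append(f"{q}\t{h}\t{ident}\t{ev}\tdb\t")
    p = tmp_path / "pairs.tsv"
    p.write_text("\n".join(lines) + "\n")
    return TableSimilarityAdapter(p)


def brute_force_mutual_best(scores, a, b):
    """Oracle: a and b are mutual best hits under (e asc, ident desc, acc)."""

    def best(q):
        cands = [(h, ident, ev) for (qq, h), (ident, ev) in scores.items()
                 if qq == q]
        if not cands:
            return None
        cands.sort(key=lambda t: (t[2], -t[1], t[0]))
        return cands[0][0]

    return best(a) == b and best(b) == a


class TestRBH:
    def test_symmetric_mutual_best_confirmed(self, tmp_path):
        scores = {("A", "B"): (90.0, 1e-40), ("B", "A"): (90.0, 1e-40),
                  ("A", "C"): (50.0, 1e-10), ("C", "A"): (50.0, 1e-10)}
        adapter = _table_adapter_from_scores(tmp_path, scores)
        hit = homology_search(adapter, "A", max_evalue=1.0)[0]
        assert hit.hit_accession == "B"
        assert rbh_confirm(adapter, "A", hit) is True

    def test_one_way_best_unconfirmed(self, tmp_path):
        scores = {("A", "B"): (90.0, 1e-40),
                  ("B", "C"): (95.0, 1e-50), ("B", "A"): (90.0, 1e-40)}
        adapter = _table_adapter_from_scores(tmp_path, scores)
        hit = [h for h in homology_search(adapter, "A", max_evalue=1.0)
               if h.hit_accession == "B"][0]
        assert rbh_confirm(adapter, "A", hit) is False

    def test_empty_reverse_search_unconfirmed(self, tmp_path):
        scores = {("A", "B"): (90.0, 1e-40)}
        adapter = _table_adapter_from_scores(tmp_path, scores)
        hit = homology_search(adapter, "A", max_evalue=1.0)[0]
        assert rbh_confirm(adapter, "A", hit) is False

    def test_agrees_with_brute_force_on_random_tables(self, tmp_path):
        rng = random.Random(2024)
        for trial in range(40):
            n = rng.randint(2, 10)
            names = [f"S{i}" for i in range(n)]
            scores = {}
            for q in names:
                for h in names:
                    if q != h and rng.random() < 0.5:
                        scores[(q, h)] = (round(rng.uniform(20, 100), 1),
                                          10 ** -rng.randint(1, 60))
            if not scores:
                continue
            adapter = _table_adapter_from_scores(tmp_path / f"t{trial}"
                                                 if False else tmp_path, scores)
            for (q, h), (ident, ev) in scores.items():
                hit = SimilarityHit(q, h, "", ident, ev)
                assert (rbh_confirm(adapter, q, hit)
                        == brute_force_mutual_best(scores, q, h))

    def test_symmetric_tables_give_symmetric_confirmation(self, tmp_path):
        rng = random.Random(99)
        for _ in range(20):
            n = rng.randint(2, 8)
            names = [f"S{i}" for i in range(n)]
            scores = {}
            for i, q in enumerate(names):
                for h in names[i + 1:]:
                    if rng.random() < 0.6:
                        val = (round(rng.uniform(20, 100), 1),
                               10 ** -rng.randint(1, 60))
                        scores[(q, h)] = val
                        scores[(h, q)] = val
            if not scores:
                continue
            adapter = _table_adapter_from_scores(tmp_path, scores)
            for (q, h), (ident, ev) in scores.items():
                fwd = rbh_confirm(adapter, q, SimilarityHit(q, h, "", ident, ev))
                rev = rbh_confirm(adapter, h, SimilarityHit(h, q, "", ident, ev))
                assert fwd == rev


class TestIntegrateHits:
    def test_confirmed_hit_integrated(self):
        g = InformationGraph()
        qid = g.add_concept("Protein", "P_query")
        hit = SimilarityHit("P_query", "CPSG_01145",
                            "citrinin biosynthesis oxidoreductase CtnB",
                            62.0, 1e-40, "uniprot")
        c, r = integrate_hits(g, qid, [hit], confirmed_only=True,
                              confirmed={"CPSG_01145"})
        assert (c, r) == (1, 1)
        cid = g.find("Protein", "CPSG_01145")
        rel = g.get_relation(qid, cid, "similar_to")
        assert rel.attributes["identity_percent"] == 62.0

    def test_zero_confirmed_zero_integrated(self):
        g = InformationGraph()
        qid = g.add_concept("Protein", "P_query")
        hit = SimilarityHit("P_query", "X", "", 50.0, 1e-10)
        assert integrate_hits(g, qid, [hit], confirmed_only=True,
                              confirmed=set()) == (0, 0)

    def test_reintegration_idempotent(self):
        g = InformationGraph()
        qid = g.add_concept("Protein", "P_query")
        hit = SimilarityHit("P_query", "X", "", 50.0, 1e-10)
        integrate_hits(g, qid, [hit])
        assert integrate_hits(g, qid, [hit]) == (0, 0)
        assert g.audit() == []

    def test_planted_adapter_truth(self, bundle):
        adapter = TableSimilarityAdapter(bundle["dir"] / "adapters"
                                         / "similarity.tsv")
        for q, h in bundle["adapter_truth"]["mutual"]:
            hit = [x for x in homology_search(adapter, q)
                   if x.hit_accession == h][0]
            assert rbh_confirm(adapter, q, hit) is True
        for q, h in bundle["adapter_truth"]["oneway"]:
            hit = [x for x in homology_search(adapter, q)
                   if x.hit_accession == h][0]
            assert rbh_confirm(adapter, q, hit) is False
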