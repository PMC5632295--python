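import math

import pytest
from citescan.formats import (CitesEntry, RefRecord, Taxonomy, TaxonNode,
                              read_hits_table, write_hits_table)
from citescan.otu import Otu
from citescan.taxassign import (Hit, RefIndex, align_search, cites_match,
                                consensus_assign, filter_hits)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def toy_taxonomy():
    """Two families, three genera, five species (plus root/order)."""
    nodes = [
        TaxonNode(1, "root", "other", 1),
        TaxonNode(2, "Ordo", "order", 1),
        TaxonNode(10, "FamA", "family", 2),
        TaxonNode(11, "FamB", "family", 2),
        TaxonNode(20, "GenA", "genus", 10),
        TaxonNode(21, "GenB", "genus", 10),
        TaxonNode(22, "GenC", "genus", 11),
        TaxonNode(30, "GenA sp1", "species", 20, ["Old sp1"]),
        TaxonNode(31, "GenA sp2", "species", 20),
        TaxonNode(32, "GenB sp1", "species", 21),
        TaxonNode(33, "GenC sp1", "species", 22),
        TaxonNode(34, "GenC sp2", "species", 22),
    ]
    return Taxonomy(nodes)


def mk_hit(taxid, bits, acc="X1", qid="q"):
    return Hit(qid, acc, 100.0, 100, 0, 0, 1, 100, 1, 100, 1e-30, bits,
               taxid)


class TestAlignSearch:
    def _otu(self, seq):
        return Otu("p_OTU1", "p", seq, 10)

    def test_identical_reference_is_perfect_top_hit(self, params, rng):
        seq = rand_seq(rng, 300)
        refs = [RefRecord("R1", seq, 30),
                RefRecord("R2", rand_seq(rng, 300), 31)]
        idx = RefIndex(refs, params.search_word_size)
        hits = align_search(self._otu(seq), idx, params)
        assert hits[0].accession == "R1"
        assert hits[0].pident == 100.0
        assert hits[0].qstart == 1 and hits[0].qend == 300

    def test_bitscore_and_evalue_formulas(self):
        # raw score 100, m=300, n=10000
        from citescan._align import bitscore, evalue
        bits = bitscore(100.0)
        assert bits == pytest.approx((1.28 * 100 - math.log(0.46))
                                     / math.log(2))
        assert bits == pytest.approx(185.8, abs=0.1)
        ev = evalue(bits, 300, 10_000)
        assert ev == pytest.approx(3e6 * 2 ** (-bits), rel=1e-9)

    def test_max_targets_cap(self, params, rng):
        base = rand_seq(rng, 300)
        refs = []
        for i in range(21):
            # i substitutions -> 21 distinct scores
            s = list(base)
            for p in range(i):
                s[p * 10] = {"A": "C", "C": "G", "G": "T",
                             "T": "A"}[s[p * 10]]
            refs.append(RefRecord(f"R{i:02d}", "".join(s), 30))
        idx = RefIndex(refs, params.search_word_size)
        hits = align_search(self._otu(base), idx, params)
        assert len(hits) == params.hit_max_targets == 20
        bits = [h.bitscore for h in hits]
        assert bits == sorted(bits, reverse=True)

    def test_evalue_decreases_as_bitscore_increases(self):
        from citescan._align import bitscore, evalue
        evs = [evalue(bitscore(s), 300, 10_000) for s in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_empty_refdb_rejected(self, params):
        with pytest.raises(ValueError, match="empty"):
            RefIndex([], params.search_word_size)


class TestFilterHits:
    def test_identity_floor(self, params):
        h = mk_hit(30, 200.0)
        h.pident = 97.9
        assert filter_hits([h], 100, params) == []
        h.pident = 98.0
        assert filter_hits([h], 100, params) == [h]

    def test_coverage_floor(self, params):
        h = mk_hit(30, 200.0)
        h.qstart, h.qend = 1, 89  # 89.9% of 99 would be below; use 99 len
        assert filter_hits([h], 99, params) == []
        h.qend = 90  # 90/99 = 90.9%
        assert filter_hits([h], 99, params) == [h]

    def test_all_passing_unchanged(self, params):
        hits = [mk_hit(30, 200.0, acc=f"A{i}") for i in range(3)]
        assert filter_hits(hits, 100, params) == hits


class TestConsensus:
    def test_three_concordant_hits_give_species(self, params):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(30, 290.0, "B"),
                mk_hit(30, 280.0, "C")]
        a = consensus_assign("q", hits, tax, params)
        assert (a.rank, a.taxon_name) == ("species", "GenA sp1")
        assert a.n_support == 3

    def test_two_hits_downgrade_to_genus(self, params):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(30, 290.0, "B")]
        a = consensus_assign("q", hits, tax, params)
        assert (a.rank, a.taxon_name) == ("genus", "GenA")

    def test_tie_between_congeners_gives_genus(self, params):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(31, 300.0, "B"),
                mk_hit(30, 250.0, "C")]
        a = consensus_assign("q", hits, tax, params)
        assert (a.rank, a.taxon_name) == ("genus", "GenA")

    def test_tie_across_genera_gives_family(self, params):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(32, 300.0, "B"),
                mk_hit(30, 250.0, "C")]
        a = consensus_assign("q", hits, tax, params)
        assert (a.rank, a.taxon_name) == ("family", "FamA")

    def test_tie_across_families_gives_order(self, params):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(33, 300.0, "B"),
                mk_hit(30, 250.0, "C")]
        a = consensus_assign("q", hits, tax, params)
        assert (a.rank, a.taxon_name) == ("order", "Ordo")

    def test_empty_hits_unassigned(self, params):
        a = consensus_assign("q", [], toy_taxonomy(), params)
        assert a.rank == "unassigned"

    def test_missing_taxid_names_accession(self, params):
        with pytest.raises(KeyError, match="ACCX"):
            consensus_assign("q", [mk_hit(999, 100.0, "ACCX")],
                             toy_taxonomy(), params)

    def test_added_tied_discordant_hit_never_raises_rank(self, params):
        """Downgrade monotonicity at the max-bitscore tie."""
        tax = toy_taxonomy()
        order = ["species", "genus", "family", "order", "unassigned"]
        base = [mk_hit(30, 300.0, "A"), mk_hit(30, 300.0, "B"),
                mk_hit(30, 300.0, "C")]
        r0 = order.index(consensus_assign("q", base, tax, params).rank)
        for other in (31, 32, 33):
            hits = base + [mk_hit(other, 300.0, "D")]
            r1 = order.index(consensus_assign("q", hits, tax, params).rank)
            assert r1 >= r0

    def test_roundtrip_through_tabular_format(self, params, tmp_path):
        tax = toy_taxonomy()
        hits = [mk_hit(30, 300.0, "A"), mk_hit(30, 290.0, "B"),
                mk_hit(31, 280.0, "C")]
        path = tmp_path / "hits.tsv"
        write_hits_table(hits, path)
        back = read_hits_table(path)
        a1 = consensus_assign("q", hits, tax, params)
        a2 = consensus_assign("q", back, tax, params)
        assert (a1.rank, a1.taxon_name, a1.n_support) \
            == (a2.rank, a2.taxon_name, a2.n_support)


class TestCitesMatch:
    def _table(self):
        return [CitesEntry("GenA sp1", "species", "II"),
                CitesEntry("GenB", "genus", "I"),
                CitesEntry("FamB", "family", "III"),
                CitesEntry("Old sp1", "species", "II")]

    def test_species_level_listing(self, params):
        tax = toy_taxonomy()
        a = consensus_assign("q", [mk_hit(30, 3.0, "A"), mk_hit(30, 2.0, "B"),
                                   mk_hit(30, 1.0, "C")], tax, params)
        call = cites_match(a, self._table(), tax)
        assert call is not None
        assert (call.entry.appendix, call.match_level) == ("II", "species")

    def test_genus_level_assignment_matches_genus_entry(self, params):
        tax = toy_taxonomy()
        a = consensus_assign("q", [mk_hit(32, 3.0, "A"), mk_hit(32, 2.0, "B")],
                             tax, params)
        assert a.rank == "genus"
        call = cites_match(a, self._table(), tax)
        assert call is not None
        assert (call.entry.listed_name, call.match_level) == ("GenB", "genus")

    def test_synonym_matching(self, params):
        tax = toy_taxonomy()
        table = [CitesEntry("Old sp1", "species", "II")]
        a = consensus_assign("q", [mk_hit(30, 3.0, "A"), mk_hit(30, 2.0, "B"),
                                   mk_hit(30, 1.0, "C")], tax, params)
        call = cites_match(a, table, tax)
        assert call is not None and call.match_level == "synonym"

    def test_unlisted_lineage_gives_none(self, params):
        tax = toy_taxonomy()
        a = consensus_assign("q", [mk_hit(31, 3.0, "A"), mk_hit(31, 2.0, "B"),
                                   mk_hit(31, 1.0, "C")], tax, params)
        assert cites_match(a, [CitesEntry("GenB", "genus", "I")], tax) is None

    def test_ancestor_listing_for_species_assignment(self, params):
        tax = toy_taxonomy()
        a = consensus_assign("q", [mk_hit(33, 3.0, "A"), mk_hit(33, 2.0, "B"),
                                   mk_hit(33, 1.0, "C")], tax, params)
        call = cites_match(a, self._table(), tax)
        assert call is not None
        assert (call.entry.listed_name, call.match_level) == ("FamB",
                                                              "family")

    def test_empty_table_gives_none(self, params):
        tax = toy_taxonomy()
        a = consensus_assign("q", [mk_hit(30, 3.0, "A"), mk_hit(30, 2.0, "B"),
                                   mk_hit(30, 1.0, "C")], tax, params)
        assert cites_match(a, [], tax) is None
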