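"""Phase 3: taxonomy prediction and CITES identification.

OTU centroids are searched against the local reference collection with a
megablast-like local aligner (match +1 / mismatch -2, linear gap 2.5;
bit score ``(lambda*S - ln K)/ln 2`` with the ungapped Karlin-Altschul
parameters lambda = 1.28, K = 0.46; E-value ``m*n*2^-bits``).  Hits are
filtered at 98% identity / 90% query coverage / E <= 0.001, then the
bit-score consensus rule assigns a rank: a species call needs the decisive
set (top three hits, widened to the full tie set at the maximum bit score)
to agree on one species; disagreement downgrades to genus, family, order,
or leaves the OTU unassigned.  Assignments are finally matched against the
local CITES listing table through the taxonomy's names, synonyms and
lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from ._align import bitscore as _bitscore
from ._align import evalue as _evalue
from ._align import smith_waterman
from .formats import (CitesEntry, PipelineParams, RefRecord, Taxonomy,
                      TaxonNode)
from .otu import Otu

logger = logging.getLogger(__name__)

_RANKS_DESCENDING = ("species", "genus", "family", "order")


@dataclass
class Hit:
    """One alignment of an OTU centroid to a reference record."""

    query_id: str
    accession: str
    pident: float
    aln_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    taxid: int

    def query_cov(self, query_len: int) -> float:
        return (self.qend - self.qstart + 1) / query_len


@dataclass
class Assignment:
    otu_id: str
    rank: str  # species | genus | family | order | unassigned
    taxon_name: str
    taxid: int
    n_support: int
    decisive_hits: list[Hit] = field(default_factory=list)
    retained_hits: list[Hit] = field(default_factory=list)


@dataclass
class CitesCall:
    assignment: Assignment
    entry: CitesEntry
    match_level: str  # species | synonym | genus | family | order


# ---------------------------------------------------------------------------
# Reference search
# ---------------------------------------------------------------------------

class RefIndex:
    """Word index over the reference collection (megablast-like seeding).

    Only references sharing at least one exact word with the query are
    aligned; this mirrors the exact-seed heuristic of the search mode the
    scoring emulates and keeps the full-database scan tractable.
    """

    def __init__(self, refdb: list[RefRecord], word_size: int = 16):
        if not refdb:
            raise ValueError("empty reference database")
        self.refdb = refdb
        self.word_size = word_size
        self.db_len = sum(len(r.seq) for r in refdb)
        self._index: dict[str, set[int]] = {}
        for i, rec in enumerate(refdb):
            seq = rec.seq
            for j in range(0, max(len(seq) - word_size + 1, 0)):
                self._index.setdefault(seq[j:j + word_size], set()).add(i)

    def candidates(self, query: str) -> list[int]:
        found: set[int] = set()
        w = self.word_size
        for j in range(0, max(len(query) - w + 1, 0)):
            hits = self._index.get(query[j:j + w])
            if hits:
                found |= hits
        return sorted(found)


def align_search(otu: Otu, index: RefIndex,
                 params: PipelineParams) -> list[Hit]:
    """Search one centroid against the reference collection.

    Reports up to ``hit_max_targets`` hits with E-value <=
    ``hit_evalue_max``, sorted by bit score descending, ties by accession.
    """
    query = otu.centroid
    m = len(query)
    hits: list[Hit] = []
    for i in index.candidates(query):
        rec = index.refdb[i]
        aln = smith_waterman(query, rec.seq, params.aln_match,
                             params.aln_mismatch, params.aln_gap)
        if aln is None:
            continue
        bits = _bitscore(aln["score"], params.aln_lambda, params.aln_k)
        ev = _evalue(bits, m, index.db_len)
        if ev > params.hit_evalue_max:
            continue
        pident = 100.0 * aln["matches"] / aln["aln_len"]
        hits.append(Hit(
            query_id=otu.otu_id, accession=rec.accession, pident=pident,
            aln_len=aln["aln_len"], mismatches=aln["mismatches"],
            gapopens=aln["gapopens"], qstart=aln["qstart"],
            qend=aln["qend"], sstart=aln["sstart"], send=aln["send"],
            evalue=ev, bitscore=bits, taxid=rec.taxid))
    hits.sort(key=lambda h: (-h.bitscore, h.accession))
    return hits[: params.hit_max_targets]


def filter_hits(hits: list[Hit], query_len: int,
                params: PipelineParams) -> list[Hit]:
    """Retain hits meeting identity, query-coverage and E-value floors."""
    return [h for h in hits
            if h.pident >= params.hit_min_identity_pct - 1e-9
            and 100.0 * h.query_cov(query_len)
            >= params.hit_min_query_cov_pct - 1e-9
            and h.evalue <= params.hit_evalue_max]


# ---------------------------------------------------------------------------
# Consensus assignment
# ---------------------------------------------------------------------------

def _rank_name(taxonomy: Taxonomy, taxid: int, rank: str) -> Optional[TaxonNode]:
    return taxonomy.lineage(taxid).get(rank)


def consensus_assign(otu_id: str, hits: list[Hit], taxonomy: Taxonomy,
                     params: PipelineParams) -> Assignment:
    """Bit-score consensus with rank downgrade.

    The decisive set is the first ``k`` hits of the bit-score-sorted list,
    where ``k = max(top_hits_required, number of hits tied at the maximum
    bit score)``.  A species assignment requires all decisive hits to map
    to one species with at least ``top_hits_required`` of them; otherwise
    the call degrades to the lowest rank on which the decisive set agrees
    (genus, family, order) and is unassigned beyond that.
    """
    if not hits:
        return Assignment(otu_id, "unassigned", "", 0, 0)
    for h in hits:
        if h.taxid not in taxonomy:
            raise KeyError(
                f"hit {h.accession}: taxid {h.taxid} missing from taxonomy")
    ordered = sorted(hits, key=lambda h: (-h.bitscore, h.accession))
    top_bits = round(ordered[0].bitscore, 2)
    n_tied = sum(1 for h in ordered if round(h.bitscore, 2) == top_bits)
    k = max(params.top_hits_required, n_tied)
    decisive = ordered[:k]

    for rank in _RANKS_DESCENDING:
        nodes = []
        ok = True
        for h in decisive:
            node = _rank_name(taxonomy, h.taxid, rank)
            if node is None:
                ok = False
                break
            nodes.append(node)
        if not ok:
            continue
        ids = {n.taxid for n in nodes}
        if len(ids) != 1:
            continue
        if rank == "species" and len(decisive) < params.top_hits_required:
            continue  # fewer than the required top hits: downgrade
        node = nodes[0]
        return Assignment(otu_id, rank, node.name, node.taxid,
                          len(decisive), decisive, list(hits))
    return Assignment(otu_id, "unassigned", "", 0, 0, decisive, list(hits))


# ---------------------------------------------------------------------------
# CITES matching
# ---------------------------------------------------------------------------

def _norm(name: str) -> str:
    return " ".join(name.split())


def cites_match(assignment: Assignment, cites_table: list[CitesEntry],
                taxonomy: Taxonomy) -> Optional[CitesCall]:
    """Match an assignment against the CITES listing table.

    The assigned taxon's lineage (species -> genus -> family -> order,
    starting at the assignment's own rank) plus the species' synonym names
    are compared, exact-string after whitespace normalization, against the
    listed names at the matching rank.  The most specific match wins;
    a species matched through a synonym is reported at level "synonym".
    """
    if assignment.rank == "unassigned" or not cites_table:
        return None
    by_key = {(_norm(e.listed_name), e.listed_rank): e for e in cites_table}
    lineage = taxonomy.lineage(assignment.taxid)
    start = _RANKS_DESCENDING.index(assignment.rank)
    for rank in _RANKS_DESCENDING[start:]:
        node = lineage.get(rank)
        if node is None:
            continue
        entry = by_key.get((_norm(node.name), rank))
        if entry is not None:
            level = rank if rank != assignment.rank else assignment.rank
            return CitesCall(assignment, entry, level)
        if rank == "species":
            for syn in node.synonyms:
                entry = by_key.get((_norm(syn), "species"))
                if entry is not None:
                    return CitesCall(assignment, entry, "synonym")
    return None
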