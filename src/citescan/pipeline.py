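"""Orchestration: pre-processing -> demultiplexing -> OTU clustering ->
taxonomy/CITES assignment -> report, with per-stage statistics.

The whole run is a pure function of (inputs, parameters): no randomness is
involved downstream of the input FASTQ files, so identical inputs and
configuration reproduce the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .demux import MarkerBin, demultiplex
from .formats import (Marker, PipelineParams, Taxonomy, load_cites_table,
                      load_marker_panel, load_refdb, load_taxonomy,
                      write_fasta, write_fastq, write_report)
from .otu import ClusterStats, Otu, cluster_pool
from .preprocess import ReadPool, preprocess_sample
from .taxassign import (Assignment, CitesCall, RefIndex, align_search,
                        cites_match, consensus_assign, filter_hits)

logger = logging.getLogger(__name__)


@dataclass
class StageStats:
    """Per-sample stage percentages (Table-3-style schema).

    ``pct_qc`` is over raw reads (a merged pseudo-read representing both of
    its mates), ``pct_assigned`` over QC (pseudo-)reads, ``pct_otu`` over
    barcode-assigned (pseudo-)reads.
    """

    sample_id: str
    raw_reads: int
    pct_qc: float
    pct_assigned: float
    pct_otu: float


def compute_stage_stats(sample_id: str, counters: dict[str, int]) -> StageStats:
    """Percentages with the stated denominators, rounded to 2 decimals."""
    raw = counters.get("raw_reads", 0)
    if raw == 0:
        logger.warning("sample %s: zero raw reads; reporting zero "
                       "percentages", sample_id)
        return StageStats(sample_id, 0, 0.0, 0.0, 0.0)
    qc_equiv = counters.get("qc_raw_equiv", counters.get("qc_pseudo_reads", 0))
    qc = counters.get("qc_pseudo_reads", 0)
    assigned = counters.get("assigned_reads", 0)
    clustered = counters.get("clustered_reads", 0)
    pct_qc = round(100.0 * qc_equiv / raw, 2)
    pct_assigned = round(100.0 * assigned / qc, 2) if qc else 0.0
    pct_otu = round(100.0 * clustered / assigned, 2) if assigned else 0.0
    return StageStats(sample_id, raw, pct_qc, pct_assigned, pct_otu)


@dataclass
class PipelineResult:
    sample_id: str
    pool: ReadPool
    bins: list[MarkerBin]
    unassigned: int
    otus: dict[str, list[Otu]]              # pool name -> kept OTUs
    cluster_stats: dict[str, ClusterStats]  # pool name -> accounting
    assignments: list[Assignment]
    cites_calls: dict[str, CitesCall]       # otu_id -> call
    report_rows: list[dict]
    stats: StageStats
    counters: dict[str, int]


def _report_rows(otus_by_pool: dict[str, list[Otu]],
                 assignments: dict[str, Assignment],
                 cites_calls: dict[str, CitesCall],
                 taxonomy: Taxonomy) -> list[dict]:
    rows = []
    for pool_name in otus_by_pool:
        for otu in otus_by_pool[pool_name]:
            a = assignments[otu.otu_id]
            call = cites_calls.get(otu.otu_id)
            base = {
                "otu_id": otu.otu_id,
                "marker_pool": otu.pool_name,
                "otu_size": otu.size,
                "abundance_frac": round(otu.abundance_frac, 6),
                "assigned_rank": a.rank,
                "assigned_name": a.taxon_name,
                "cites_appendix": call.entry.appendix if call else "",
                "cites_listed_name": call.entry.listed_name if call else "",
                "cites_listed_rank": call.entry.listed_rank if call else "",
            }
            if not a.retained_hits:
                rows.append(base)
                continue
            qlen = len(otu.centroid)
            for h in a.retained_hits:
                row = dict(base)
                node = taxonomy.node(h.taxid)
                row.update({
                    "accession": h.accession,
                    "pident": round(h.pident, 3),
                    "query_cov_pct": round(100.0 * h.query_cov(qlen), 2),
                    "bitscore": round(h.bitscore, 2),
                    "evalue": h.evalue,
                    "scientific_name": node.name,
                    "synonym_names": ";".join(node.synonyms),
                })
                rows.append(row)
    return rows


def run_pipeline(fwd_fastq, rev_fastq, refdb_fasta, acc2taxid, taxonomy_path,
                 cites_path, out_dir, params: Optional[PipelineParams] = None,
                 panel_path=None, sample_id: str = "sample",
                 keep_intermediates: bool = False) -> PipelineResult:
    """Run the three pipeline phases on one paired-end sample.

    Writes ``report.tsv`` and ``stats.tsv`` under ``out_dir`` (plus
    intermediate FASTQ/FASTA streams when ``keep_intermediates``), and
    returns the full in-memory result.
    """
    params = params or PipelineParams()
    params.validate()
    for p in (fwd_fastq, rev_fastq, refdb_fasta, acc2taxid, taxonomy_path,
              cites_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in dataclasses.fields(params):
        logger.info("param %s = %r", f.name, getattr(params, f.name))

    panel = load_marker_panel(panel_path)
    taxonomy = load_taxonomy(taxonomy_path)
    refdb = load_refdb(refdb_fasta, acc2taxid, taxonomy)
    cites = load_cites_table(cites_path)

    # phase 1: QC + demultiplex
    pool = preprocess_sample(fwd_fastq, rev_fastq, params)
    logger.info("QC: %s", pool.counters)
    bins, unassigned = demultiplex(pool, panel, params)
    if keep_intermediates:
        write_fastq(pool.merged, out / "merged.fastq")
        write_fastq(pool.fwd_unmerged, out / "unmerged_fwd.fastq")
        write_fastq(pool.rev_unmerged, out / "unmerged_rev.fastq")

    # phase 2: per-pool OTUs
    markers_by_pool: dict[str, list[Marker]] = {}
    for m in panel:
        markers_by_pool.setdefault(m.pool_name, []).append(m)
    otus_by_pool: dict[str, list[Otu]] = {}
    cstats: dict[str, ClusterStats] = {}
    for b in bins:
        otus, st = cluster_pool(b.reads, b.pool_name,
                                markers_by_pool[b.pool_name], params)
        otus_by_pool[b.pool_name] = otus
        cstats[b.pool_name] = st
        logger.info("pool %s: %d reads -> %d OTUs", b.pool_name,
                    b.n_assigned, len(otus))
    if keep_intermediates:
        for pool_name, otus in otus_by_pool.items():
            if otus:
                safe = pool_name.replace(" ", "_")
                write_fasta(((f"{o.otu_id};size={o.size}", o.centroid)
                             for o in otus), out / f"otus_{safe}.fasta")

    # phase 3: taxonomy + CITES
    index = RefIndex(refdb, params.search_word_size)
    assignments: dict[str, Assignment] = {}
    cites_calls: dict[str, CitesCall] = {}
    for pool_name, otus in otus_by_pool.items():
        for otu in otus:
            hits = align_search(otu, index, params)
            retained = filter_hits(hits, len(otu.centroid), params)
            a = consensus_assign(otu.otu_id, retained, taxonomy, params)
            a.retained_hits = retained
            assignments[otu.otu_id] = a
            call = cites_match(a, cites, taxonomy)
            if call is not None:
                cites_calls[otu.otu_id] = call

    rows = _report_rows(otus_by_pool, assignments, cites_calls, taxonomy)
    write_report(rows, out / "report.tsv")

    counters = dict(pool.counters)
    counters["assigned_reads"] = sum(b.n_assigned for b in bins)
    counters["unassigned_reads"] = unassigned
    counters["clustered_reads"] = sum(st.clustered for st in cstats.values())
    stats = compute_stage_stats(sample_id, counters)
    with open(out / "stats.tsv", "w") as fh:
        fh.write("sample_id\traw_reads\tpct_qc\tpct_assigned\tpct_otu\n")
        fh.write(f"{stats.sample_id}\t{stats.raw_reads}\t{stats.pct_qc:.2f}"
                 f"\t{stats.pct_assigned:.2f}\t{stats.pct_otu:.2f}\n")

    return PipelineResult(
        sample_id=sample_id, pool=pool, bins=bins, unassigned=unassigned,
        otus=otus_by_pool, cluster_stats=cstats,
        assignments=list(assignments.values()), cites_calls=cites_calls,
        report_rows=rows, stats=stats, counters=counters)
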