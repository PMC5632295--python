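"""Phase 1a: read pre-processing.

Order of operations is fixed: Illumina overhang/adapter trimming on both
mates, removal of very short reads, pair merging into pseudo-reads, then
sliding-window quality trimming and the per-base quality-fraction filter
applied independently to merged, unmerged-forward and unmerged-reverse
streams.  A merged pseudo-read carries one sequence and one set of quality
scores; in the overlap the higher-quality base wins, with quality
``|q1 - q2|`` at disagreeing positions and the maximum at agreeing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._align import find_adapter_3p, find_adapter_5p, revcomp
from .formats import NucRead, PipelineParams, parse_fastq


@dataclass
class ReadPool:
    """QC output: merged pseudo-reads plus surviving unmerged mates."""

    merged: list[NucRead] = field(default_factory=list)
    fwd_unmerged: list[NucRead] = field(default_factory=list)
    rev_unmerged: list[NucRead] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def reads(self) -> list[NucRead]:
        """All (pseudo-)reads in a fixed order: merged, fwd, rev."""
        return self.merged + self.fwd_unmerged + self.rev_unmerged

    def __len__(self) -> int:
        return len(self.merged) + len(self.fwd_unmerged) + len(self.rev_unmerged)


# ---------------------------------------------------------------------------
# Individual operations
# ---------------------------------------------------------------------------

def trim_adapters(read: NucRead, params: PipelineParams) -> Optional[NucRead]:
    """Trim the 5' and 3' Illumina adapter substrings; drop short leftovers.

    If the 5' substring occurs (error-tolerantly), everything up to and
    including it is removed; if the 3' substring occurs, it and everything
    after is removed.  Reads of length <= ``min_read_len`` are dropped
    (None).  A read with no adapter occurrence is returned unchanged.
    """
    seq, quals = read.seq, read.quals
    cut5 = find_adapter_5p(seq, params.adapter_5p, params.adapter_error_rate)
    if cut5 is not None:
        seq, quals = seq[cut5:], quals[cut5:]
    cut3 = find_adapter_3p(seq, params.adapter_3p, params.adapter_error_rate)
    if cut3 is not None:
        seq, quals = seq[:cut3], quals[:cut3]
    if len(seq) <= params.min_read_len:
        return None
    return NucRead(read.read_id, seq, list(quals))


def merge_pair(fwd: NucRead, rev: NucRead,
               params: PipelineParams) -> tuple[Optional[NucRead],
                                                Optional[tuple[NucRead, NucRead]]]:
    """Merge a pair into a pseudo-read via the best ungapped overlap.

    The reverse mate is reverse-complemented; the ungapped suffix(fwd) /
    prefix(revcomp(rev)) overlap of length >= ``merge_min_overlap``
    minimizing the mismatch fraction is taken, and the pair merges when that
    fraction is <= ``merge_max_mismatch_frac``.  Returns ``(merged, None)``
    or ``(None, (fwd, rev))``.
    """
    rc_seq = revcomp(rev.seq)
    rc_quals = rev.quals[::-1]
    lf, lr = len(fwd), len(rc_seq)
    if lf == 0 or lr == 0 or min(lf, lr) < params.merge_min_overlap:
        return None, (fwd, rev)

    f = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc_seq.encode(), dtype=np.uint8)

    def mism(o: int) -> int:
        return int((f[lf - o:] != r[:o]).sum())

    # seed candidate overlaps from exact 16-mer hits before the full scan
    candidates: set[int] = set()
    seed = rc_seq[:16]
    start = 0
    while True:
        pos = fwd.seq.find(seed, start)
        if pos < 0:
            break
        candidates.add(lf - pos)
        start = pos + 1
    seed2 = fwd.seq[-16:]
    start = 0
    while True:
        pos = rc_seq.find(seed2, start)
        if pos < 0:
            break
        candidates.add(pos + 16)
        start = pos + 1
    candidates = {o for o in candidates
                  if params.merge_min_overlap <= o <= min(lf, lr)}

    best: Optional[tuple[float, int]] = None  # (mismatch_frac, -overlap)
    scan = sorted(candidates) or range(params.merge_min_overlap,
                                       min(lf, lr) + 1)
    for _pass in range(2):
        for o in scan:
            frac = mism(o) / o
            if frac <= params.merge_max_mismatch_frac:
                cand = (frac, -o)
                if best is None or cand < best:
                    best = cand
        if best is not None or not candidates:
            break
        scan = range(params.merge_min_overlap, min(lf, lr) + 1)

    if best is None:
        return None, (fwd, rev)
    o = -best[1]
    head_seq, head_q = fwd.seq[: lf - o], fwd.quals[: lf - o]
    tail_seq, tail_q = rc_seq[o:], rc_quals[o:]
    mid_seq: list[str] = []
    mid_q: list[int] = []
    for i in range(o):
        bf, bq = fwd.seq[lf - o + i], fwd.quals[lf - o + i]
        rb, rq = rc_seq[i], rc_quals[i]
        if bf == rb:
            mid_seq.append(bf)
            mid_q.append(max(bq, rq))
        elif bq >= rq:
            mid_seq.append(bf)
            mid_q.append(abs(bq - rq))
        else:
            mid_seq.append(rb)
            mid_q.append(abs(bq - rq))
    merged = NucRead(fwd.read_id, head_seq + "".join(mid_seq) + tail_seq,
                     head_q + mid_q + tail_q)
    return merged, None


def window_trim(read: NucRead, params: PipelineParams) -> NucRead:
    """3'-end sliding-window quality trimming.

    Windows of ``window`` nt start at offsets 0, step, 2*step, ...; the
    first window whose mean quality is below ``trim_q`` truncates the read
    at that window's start.  Reads shorter than one window are evaluated as
    a single whole-read window; windows are clipped at the read end.
    """
    n = len(read)
    if n == 0:
        return read
    q = np.asarray(read.quals, dtype=np.float64)
    cs = np.concatenate(([0.0], np.cumsum(q)))
    off = 0
    while off < n:
        end = min(off + params.window, n)
        mean = (cs[end] - cs[off]) / (end - off)
        if mean < params.trim_q:
            return read.slice(0, off)
        off += params.step
    return read


def fraction_filter(read: NucRead, params: PipelineParams) -> bool:
    """Keep iff the fraction of bases with Q >= trim_q reaches frac_q20."""
    n = len(read)
    if n == 0:
        return False
    good = sum(1 for q in read.quals if q >= params.trim_q)
    return good >= params.frac_q20 * n - 1e-9


# ---------------------------------------------------------------------------
# Per-sample driver
# ---------------------------------------------------------------------------

def _qc_stream(reads: Iterable[NucRead],
               params: PipelineParams) -> list[NucRead]:
    out = []
    for r in reads:
        t = window_trim(r, params)
        if fraction_filter(t, params):
            out.append(t)
    return out


def preprocess_sample(fwd_path, rev_path, params: PipelineParams) -> ReadPool:
    """Run the full pre-processing phase on one paired FASTQ sample."""
    fwd_reads = list(parse_fastq(fwd_path))
    rev_reads = list(parse_fastq(rev_path))
    if len(fwd_reads) != len(rev_reads):
        raise ValueError(
            f"mate count mismatch: {len(fwd_reads)} forward vs "
            f"{len(rev_reads)} reverse reads")
    raw = len(fwd_reads) + len(rev_reads)

    merged_in: list[NucRead] = []
    fwd_in: list[NucRead] = []
    rev_in: list[NucRead] = []
    post_adapter = 0
    for f, r in zip(fwd_reads, rev_reads):
        tf = trim_adapters(f, params)
        tr = trim_adapters(r, params)
        post_adapter += (tf is not None) + (tr is not None)
        if tf is not None and tr is not None:
            m, pair = merge_pair(tf, tr, params)
            if m is not None:
                merged_in.append(m)
            else:
                fwd_in.append(tf)
                rev_in.append(tr)
        elif tf is not None:
            fwd_in.append(tf)
        elif tr is not None:
            rev_in.append(tr)

    # both mates of an unmerged pair count as independent (pseudo-)reads
    # by default; the switch keeps only the forward mate instead
    if not params.count_both_unmerged_mates:
        rev_in = []
    pool = ReadPool(
        merged=_qc_stream(merged_in, params),
        fwd_unmerged=_qc_stream(fwd_in, params),
        rev_unmerged=_qc_stream(rev_in, params),
    )
    # raw-read equivalents: a merged pseudo-read stands for both its mates
    qc_raw_equiv = 2 * len(pool.merged) + len(pool.fwd_unmerged) \
        + len(pool.rev_unmerged)
    pool.counters = {
        "raw_reads": raw,
        "post_adapter_reads": post_adapter,
        "merged_pairs": len(merged_in),
        "post_merge_pseudo_reads": len(merged_in) + len(fwd_in) + len(rev_in),
        "qc_pseudo_reads": len(pool),
        "qc_raw_equiv": qc_raw_equiv,
    }
    return pool
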