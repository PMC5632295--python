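"""Phase 1b: primer-based selection, trimming and sorting of (pseudo-)reads.

Each read is tested marker by marker, in panel order, against the marker's
forward primers as-is and its reverse primers (a reverse-strand read starts
with a reverse primer at its 5' end).  The first matching marker wins; the
matched primer span is removed, any opposite-orientation primer present at
the 3' end is removed too, reverse-strand reads are flipped into forward
orientation, and the read lands in the marker's *pool* (mini-COI pools with
COI, mini-cyt b with cyt b, because those loci share selection primers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import edlib

from ._align import (IUPAC_EQUALITIES, match_anchored_5p, match_suffix_3p,
                     revcomp)
from .formats import Marker, NucRead, PipelineParams
from .preprocess import ReadPool

logger = logging.getLogger(__name__)


@dataclass
class PrimerMatch:
    marker_name: str
    primer: str
    orientation: str  # "forward-primer" | "reverse-primer"
    errors: int
    match_end: int  # 0-based exclusive end offset of the matched span


@dataclass
class MarkerBin:
    pool_name: str
    reads: list[NucRead] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return len(self.reads)


def match_primer_5p(read: NucRead, primer: str, params: PipelineParams,
                    marker_name: str = "", orientation: str = "forward-primer",
                    ) -> Optional[PrimerMatch]:
    """Anchored 5' primer match with error tolerance.

    Unit-cost edit distance; degenerate IUPAC codes match their base set at
    zero cost; a span of the primer (full, or a 5'-truncated suffix of at
    least ``primer_min_overlap`` nt) must align at the read start with at
    most ``floor(primer_error_rate * span)`` errors.
    """
    hit = match_anchored_5p(primer, read.seq, params.primer_error_rate,
                            params.primer_min_overlap)
    if hit is None:
        return None
    end, errors, span = hit
    assert errors <= math.floor(params.primer_error_rate * span)
    return PrimerMatch(marker_name, primer, orientation, errors, end)


def trim_primer_3p(read: NucRead, opposite_primers: list[str],
                   params: PipelineParams) -> NucRead:
    """Remove the reverse complement of any opposite-orientation primer
    found toward the read's 3' end, together with everything after it
    (standard 3'-adapter trimmer semantics: a full occurrence may sit
    anywhere in the read -- read-through into downstream sequence is cut
    away with it -- and partial occurrences at the very end are honoured
    down to ``primer_min_overlap`` nt, all at the primer error tolerance)."""
    best_cut: int | None = None
    for primer in opposite_primers:
        target = revcomp(primer)
        k = math.floor(params.primer_error_rate * len(target))
        res = edlib.align(target, read.seq, mode="HW", task="locations", k=k,
                          additionalEqualities=IUPAC_EQUALITIES)
        if res["editDistance"] >= 0:
            end = min(loc[1] for loc in res["locations"])
            res2 = edlib.align(target, read.seq[: end + 1], mode="HW",
                               task="path", k=k,
                               additionalEqualities=IUPAC_EQUALITIES)
            cut = res2["locations"][0][0]
        else:
            cut = match_suffix_3p(target, read.seq,
                                  params.primer_error_rate,
                                  params.primer_min_overlap)
        if cut is not None and (best_cut is None or cut < best_cut):
            best_cut = cut
    if best_cut is not None:
        return read.slice(0, best_cut)
    return read


def _pool_primers(panel: list[Marker]) -> dict[str, tuple[list[str], list[str]]]:
    """Union of (fwd, rev) primers per pool: pooled loci share selection
    primers on one side but differ on the other, so 3' trimming must know
    every opposite primer of the pool."""
    out: dict[str, tuple[list[str], list[str]]] = {}
    for m in panel:
        fwd, rev = out.setdefault(m.pool_name, ([], []))
        fwd.extend(p for p in m.fwd_primers if p not in fwd)
        rev.extend(p for p in m.rev_primers if p not in rev)
    return out


def _assign_read(read: NucRead, panel: list[Marker],
                 pool_primers: dict[str, tuple[list[str], list[str]]],
                 params: PipelineParams) -> Optional[tuple[Marker, NucRead]]:
    """Best-match assignment over the panel.

    All full-length anchored primer matches across the whole panel compete
    first; the lowest error fraction wins (ties: longer matched span, then
    panel order, forward before reverse primers).  Only when no full
    primer matches anywhere are truncated anchors considered, under the
    same competition.  Degenerate cocktail primers are tolerant enough
    that a pure first-match rule would capture foreign loci; making
    matches compete keeps each read with its own locus while preserving
    the panel-order tie-break.
    """
    best = None  # (err_frac, -span, marker_idx, orientation_idx, primer_idx)
    best_hit: Optional[tuple[Marker, int, int]] = None
    for truncated in (False, True):
        for midx, marker in enumerate(panel):
            for oidx, plist in enumerate((marker.fwd_primers,
                                          marker.rev_primers)):
                for pidx, primer in enumerate(plist):
                    hit = match_anchored_5p(
                        primer, read.seq, params.primer_error_rate,
                        params.primer_min_overlap, allow_truncated=truncated)
                    if hit is None:
                        continue
                    end, errors, span = hit
                    key = (errors / span, -span, midx, oidx, pidx)
                    if best is None or key < best:
                        best = key
                        best_hit = (marker, oidx, end)
        if best_hit is not None:
            break
    if best_hit is None:
        return None
    marker, oidx, end = best_hit
    pool_fwd, pool_rev = pool_primers[marker.pool_name]
    trimmed = read.slice(end)
    if oidx == 0:  # forward primer at 5' end
        return marker, trim_primer_3p(trimmed, pool_rev, params)
    trimmed = trim_primer_3p(trimmed, pool_fwd, params)
    return marker, NucRead(trimmed.read_id, revcomp(trimmed.seq),
                           trimmed.quals[::-1])


def demultiplex(pool: ReadPool, panel: list[Marker],
                params: PipelineParams) -> tuple[list[MarkerBin], int]:
    """Sort (pseudo-)reads into per-marker pools.

    Returns the bins (one per distinct pool name, panel order) and the
    number of unassigned reads.  Reads of <= ``min_read_len`` nt after
    primer trimming are dropped (counted as unassigned);
    ``n_assigned`` summed over bins + unassigned == pool size.
    """
    bins: dict[str, MarkerBin] = {}
    for marker in panel:
        bins.setdefault(marker.pool_name, MarkerBin(marker.pool_name))
    pool_primers = _pool_primers(panel)
    unassigned = 0
    for read in pool.reads():
        res = _assign_read(read, panel, pool_primers, params)
        if res is None:
            unassigned += 1
            continue
        marker, trimmed = res
        if len(trimmed) <= params.min_read_len:
            unassigned += 1
            continue
        bins[marker.pool_name].reads.append(trimmed)
    out = list(bins.values())
    n_assigned = sum(b.n_assigned for b in out)
    logger.info("demultiplex: %d assigned, %d unassigned across %d pools",
                n_assigned, unassigned, len(out))
    return out, unassigned
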