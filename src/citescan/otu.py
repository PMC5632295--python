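"""Phase 2: per-pool OTU construction.

Reads are prefix-dereplicated (identical sequences and exact prefixes of
longer sequences collapse into one counted unique; groups below the minimum
cluster size are discarded), then clustered greedily by abundance into
centroids at a fixed identity radius (radius 2 = 98% identity).  Candidates
that fail to join an existing centroid are screened against a two-parent
chimera model before founding a new centroid.  Accepted OTUs are finally
thresholded on abundance (fraction of the pool's assigned reads) and on the
marker's minimum barcode length.

Identity here is pinned as: matches divided by alignment columns of an
end-gap-free global alignment (terminal gaps excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._align import overlap_align
from .formats import Marker, NucRead, PipelineParams

logger = logging.getLogger(__name__)


@dataclass
class UniqueSeq:
    seq: str
    size: int


@dataclass
class Otu:
    otu_id: str
    pool_name: str
    centroid: str
    size: int
    abundance_frac: float = 0.0
    members: list[UniqueSeq] = field(default_factory=list)


@dataclass
class ClusterStats:
    """Read accounting for one pool; used for conservation checks."""

    bin_size: int = 0
    derep_discarded: int = 0
    chimera_discarded: int = 0
    subthreshold_discarded: int = 0
    clustered: int = 0


def derep_prefix(reads: list[NucRead] | list[str],
                 params: PipelineParams) -> list[UniqueSeq]:
    """Prefix dereplication with minimum-cluster-size filtering.

    A sequence that is an exact prefix of a longer one merges into the
    longer one's group; the representative is the longest sequence (ties:
    higher count, then lexicographic).  Groups smaller than
    ``derep_min_size`` are discarded.  Output sorted by size descending,
    ties lexicographic by sequence.
    """
    counts: dict[str, int] = {}
    for r in reads:
        s = r if isinstance(r, str) else r.seq
        counts[s] = counts.get(s, 0) + 1
    # longest first so every prefix finds its longest extension;
    # ties by higher count then lexicographic, making the merge target
    # deterministic
    ordered = sorted(counts, key=lambda s: (-len(s), -counts[s], s))
    groups: dict[str, int] = {}
    reps: list[str] = []
    for s in ordered:
        target = None
        for rep in reps:
            if rep.startswith(s):
                target = rep
                break
        if target is None:
            reps.append(s)
            groups[s] = counts[s]
        else:
            groups[target] += counts[s]
    out = [UniqueSeq(s, n) for s, n in groups.items()
           if n >= params.derep_min_size]
    out.sort(key=lambda u: (-u.size, u.seq))
    return out


def identity_to(candidate: str, centroid: str) -> float:
    """Percent identity under the pinned end-gap-free definition."""
    return overlap_align(candidate, centroid)["identity"]


def is_chimeric(candidate: str, centroids: list[str],
                params: PipelineParams) -> bool:
    """Two-parent, single-crossover chimera model.

    True iff some pair of distinct centroids (all more abundant than the
    candidate, by construction of the greedy pass) admits a crossover
    position splitting the candidate into two segments of at least
    ``chimera_min_segment`` nt such that the two-segment model reaches
    ``chimera_min_model_identity`` percent identity to the candidate and
    exceeds the best single-centroid identity by ``chimera_margin`` points.

    Identities here are measured ungapped in candidate coordinates (the
    fraction of candidate positions equal to the parent base at the same
    position): chimera formation by template switching preserves the
    coordinate frame when divergence is substitution-dominated, and an
    ungapped profile keeps the per-position prefix decomposition exact.
    """
    n = len(candidate)
    if n < 2 * params.chimera_min_segment or len(centroids) < 2:
        return False
    cv = np.frombuffer(candidate.encode(), dtype=np.uint8)
    profiles = []
    singles = []
    for c in centroids:
        m = min(n, len(c))
        prof = np.zeros(n, dtype=np.int64)
        prof[:m] = (cv[:m] == np.frombuffer(c.encode(), dtype=np.uint8)[:m])
        profiles.append(np.concatenate(([0], np.cumsum(prof))))
        singles.append(100.0 * prof.sum() / n)
    best_single = max(singles)
    lo, hi = params.chimera_min_segment, n - params.chimera_min_segment
    xs = np.arange(lo, hi + 1)
    for a in range(len(centroids)):
        ca = profiles[a]
        for b in range(len(centroids)):
            if a == b:
                continue
            cb = profiles[b]
            model = ca[xs] + (cb[-1] - cb[xs])
            ident = 100.0 * model.max() / n
            if (ident >= params.chimera_min_model_identity
                    and ident >= best_single + params.chimera_margin):
                return True
    return False


def cluster_greedy(uniques: list[UniqueSeq], params: PipelineParams,
                   pool_name: str = "",
                   stats: ClusterStats | None = None) -> list[Otu]:
    """Abundance-sorted greedy centroid clustering at the OTU radius.

    Uniques are processed largest first; each candidate joins the existing
    centroid of highest identity if that identity is within the radius
    (>= 100 - otu_radius_pct), otherwise it is chimera-screened and, if
    clean, founds a new centroid.
    """
    ordered = sorted(uniques, key=lambda u: (-u.size, u.seq))
    otus: list[Otu] = []
    min_ident = 100.0 - params.otu_radius_pct
    for u in ordered:
        best_i, best_ident = -1, -1.0
        for i, o in enumerate(otus):
            ident = identity_to(u.seq, o.centroid)
            if ident > best_ident:
                best_i, best_ident = i, ident
        if best_i >= 0 and best_ident >= min_ident:
            otus[best_i].size += u.size
            otus[best_i].members.append(u)
            continue
        if is_chimeric(u.seq, [o.centroid for o in otus], params):
            if stats is not None:
                stats.chimera_discarded += u.size
            logger.debug("chimera discarded in pool %s (size %d)",
                         pool_name, u.size)
            continue
        otus.append(Otu(otu_id=f"{pool_name}_OTU{len(otus) + 1}",
                        pool_name=pool_name, centroid=u.seq, size=u.size,
                        members=[u]))
    return otus


def filter_otus(otus: list[Otu], marker_min_len: int, pool_total: int,
                params: PipelineParams,
                stats: ClusterStats | None = None) -> list[Otu]:
    """Keep OTUs meeting the abundance threshold (inclusive) and the
    marker's minimum barcode length; records abundance fractions."""
    if pool_total == 0:
        if otus:
            raise ValueError("non-empty OTU set with zero assigned reads")
        return []
    kept = []
    for o in otus:
        o.abundance_frac = o.size / pool_total
        if (o.size >= params.otu_abundance_frac * pool_total - 1e-9
                and len(o.centroid) >= marker_min_len):
            kept.append(o)
        elif stats is not None:
            stats.subthreshold_discarded += o.size
    return kept


def cluster_pool(reads: list[NucRead], pool_name: str, markers: list[Marker],
                 params: PipelineParams) -> tuple[list[Otu], ClusterStats]:
    """Full phase-2 run for one marker pool; returns OTUs and accounting.

    The length floor for a pooled bin is the smallest floor among its
    member markers (they coincide for the panel's pooled loci).
    """
    stats = ClusterStats(bin_size=len(reads))
    uniques = derep_prefix(reads, params)
    stats.derep_discarded = stats.bin_size - sum(u.size for u in uniques)
    otus = cluster_greedy(uniques, params, pool_name, stats)
    min_len = min((m.min_barcode_len for m in markers),
                  default=params.default_min_barcode_len)
    kept = filter_otus(otus, min_len, len(reads), params, stats) \
        if reads else []
    stats.clustered = sum(o.size for o in kept)
    return kept, stats
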