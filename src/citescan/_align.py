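"""Shared alignment primitives.

Everything error-tolerant in the pipeline funnels through here:

* anchored 5' primer matching (unit-cost edit distance, IUPAC-aware,
  truncated anchors allowed down to a minimum overlap),
* adapter-occurrence search (infix match plus partial terminal hits),
* end-gap-free global ("overlap") alignment with an explicit identity
  definition: matches / alignment columns, terminal gaps excluded,
* a Smith-Waterman local aligner with megablast-like scoring used by the
  taxonomy search stage.

edlib does the heavy lifting for the edit-distance searches; the two
scored aligners are numpy row-DP implementations (the identity definition
and the scoring constants are part of this package's contract, so they are
implemented here rather than borrowed).
"""

from __future__ import annotations

import math

import edlib
import numpy as np

IUPAC_SETS: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: symmetric pairs of IUPAC codes whose base sets intersect; passed to edlib
#: so that degenerate primer positions match at zero cost.
IUPAC_EQUALITIES: list[tuple[str, str]] = [
    (a, b)
    for a in IUPAC_SETS
    for b in IUPAC_SETS
    if a != b and IUPAC_SETS[a] & IUPAC_SETS[b]
]

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_eq(a: str, b: str) -> bool:
    """True if two IUPAC codes share at least one concrete base."""
    sa = IUPAC_SETS.get(a)
    sb = IUPAC_SETS.get(b)
    if sa is None or sb is None:
        return a == b
    return bool(sa & sb)


# ---------------------------------------------------------------------------
# Anchored primer matching
# ---------------------------------------------------------------------------

def _edlib_prefix(query: str, target: str, k: int):
    """Align full query to a prefix of target (SHW); (distance, end) or None."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="SHW", task="locations", k=k,
                      additionalEqualities=IUPAC_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    end = res["locations"][0][1]
    return res["editDistance"], end + 1  # end exclusive


def match_anchored_5p(primer: str, read: str, error_rate: float,
                      min_overlap: int,
                      allow_truncated: bool = True) -> tuple[int, int, int] | None:
    """Match ``primer`` at the very start of ``read``.

    The full primer is tried first (global on the primer, free gaps only
    after its end in the read) with a unit-cost edit budget of
    ``floor(error_rate * primer length)``.  If that fails, truncated
    anchors are tried: suffixes of the primer of length >= ``min_overlap``
    (longest first), emulating a primer whose 5' portion was clipped
    upstream.  Truncated spans must match exactly (IUPAC-aware, zero
    errors): allowing errors on short spans makes random sequence match
    some primer tail far too often for specific selection.

    Returns ``(match_end, errors, span)`` with ``match_end`` the 0-based
    exclusive read offset to cut at, or None.
    """
    lp = len(primer)
    if lp == 0 or not read:
        return None
    k = math.floor(error_rate * lp)
    window = read[: lp + k + 2]
    hit = _edlib_prefix(primer, window, k)
    if hit is not None:
        return hit[1], hit[0], lp
    if allow_truncated and lp > min_overlap:
        max_span = min(lp - 1, len(read))
        for span in range(max_span, min_overlap - 1, -1):
            tail = primer[lp - span:]
            if all(iupac_eq(a, b) for a, b in zip(tail, read[:span])):
                return span, 0, span
    return None


def match_suffix_3p(primer_rc: str, read: str, error_rate: float,
                    min_overlap: int) -> int | None:
    """Find ``primer_rc`` (or a 5'-truncated tail of the read ending inside
    it) at the 3' end of ``read``; returns the 0-based read offset at which
    to truncate, or None.

    Implemented by reduction to the anchored 5' matcher on reverse
    complements: the read ends with a prefix of ``primer_rc`` iff the
    reverse complement of the read starts with a suffix of
    ``revcomp(primer_rc)``.
    """
    hit = match_anchored_5p(revcomp(primer_rc), revcomp(read), error_rate,
                            min_overlap)
    if hit is None:
        return None
    return len(read) - hit[0]


# ---------------------------------------------------------------------------
# Adapter occurrence search
# ---------------------------------------------------------------------------

def find_adapter_5p(read: str, adapter: str, error_rate: float = 0.1,
                    min_terminal_overlap: int = 3) -> int | None:
    """Rightmost error-tolerant occurrence of ``adapter``; returns the
    exclusive end offset of the occurrence (everything up to and including
    it is to be removed), or None.

    Partial occurrences overhanging the read start (read begins inside the
    adapter) are honoured down to ``min_terminal_overlap`` nt.
    """
    k = math.floor(error_rate * len(adapter))
    res = edlib.align(adapter, read, mode="HW", task="locations", k=k)
    if res["editDistance"] >= 0:
        return max(loc[1] for loc in res["locations"]) + 1
    # partial: adapter suffix at read start
    la = len(adapter)
    for span in range(la - 1, min_terminal_overlap - 1, -1):
        kk = math.floor(error_rate * span)
        if read[:span] == adapter[la - span:]:
            return span
        if kk > 0:
            res = edlib.align(adapter[la - span:], read[: span + kk], mode="SHW",
                              task="locations", k=kk)
            if res["editDistance"] >= 0:
                return res["locations"][0][1] + 1
    return None


def find_adapter_3p(read: str, adapter: str, error_rate: float = 0.1,
                    min_terminal_overlap: int = 3) -> int | None:
    """Leftmost occurrence of ``adapter``; returns the start offset of the
    occurrence (it and everything after is to be removed), or None.
    Partial occurrences at the read 3' end are honoured down to
    ``min_terminal_overlap`` nt."""
    k = math.floor(error_rate * len(adapter))
    res = edlib.align(adapter, read, mode="HW", task="locations", k=k)
    if res["editDistance"] >= 0:
        # edlib reports end locations; recover starts via path on best hit
        best = min(loc[1] for loc in res["locations"])
        res2 = edlib.align(adapter, read[: best + 1], mode="HW", task="path", k=k)
        return res2["locations"][0][0]
    lr = len(read)
    for span in range(min(len(adapter) - 1, lr), min_terminal_overlap - 1, -1):
        kk = math.floor(error_rate * span)
        if read[lr - span:] == adapter[:span]:
            return lr - span
        if kk > 0:
            res = edlib.align(adapter[:span], read[lr - span:], mode="SHW",
                              task="locations", k=kk)
            # require the match to consume the whole read tail (terminal hit)
            if res["editDistance"] >= 0 and res["locations"][0][1] + 1 >= span - kk:
                return lr - span
    return None


# ---------------------------------------------------------------------------
# End-gap-free global ("overlap") alignment
# ---------------------------------------------------------------------------

def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def overlap_align(a: str, b: str) -> dict:
    """Global alignment of ``a`` vs ``b`` with free terminal gaps on the
    longer sequence only (unit-cost edits).

    The shorter sequence is aligned end to end; the longer one may
    contribute free unaligned overhangs.  This keeps identity meaningful
    both for containment (a read inside a longer centroid scores on its
    full length) and for same-length comparisons (which degenerate to a
    plain global alignment), while never rewarding chance micro-overlaps
    between unrelated sequences.

    Returns ``identity`` (percent = matches / alignment columns, the free
    terminal gaps excluded), ``matches``, ``columns`` and ``profile``: a
    0/1 array over positions of ``a`` marking positions aligned to an
    identical base of ``b``.
    """
    n_a, n_b = len(a), len(b)
    prof = np.zeros(n_a, dtype=np.uint8)
    if n_a == 0 or n_b == 0:
        return {"identity": 0.0, "matches": 0, "columns": max(n_a, n_b),
                "profile": prof}
    swapped = n_a > n_b
    q, t = (b, a) if swapped else (a, b)
    n, m = len(q), len(t)
    qv, tv = _as_bytes(q), _as_bytes(t)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0, :] = 0
    D[:, 0] = np.arange(n + 1)
    jcol = np.arange(m)
    offs = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = (tv != qv[i - 1]).astype(np.int32)
        cand = np.minimum(D[i - 1, :-1] + sub, D[i - 1, 1:] + 1)
        # left-to-right resolution: cur[j] = min over j' <= j of
        # cand[j'-1] + (j - j'), seeded by the penalized column 0 (= i)
        base = np.concatenate(([np.int32(i)], cand))
        acc = np.minimum.accumulate(base - offs)
        D[i, 0] = i
        D[i, 1:] = acc[1:] + offs[1:]
    # end anywhere on the last row (query fully consumed, target suffix free)
    jbest = int(np.argmin(D[n, :]))
    # prefer the rightmost end among ties for determinism with containment
    best_val = D[n, jbest]
    ties = np.flatnonzero(D[n, :] == best_val)
    jbest = int(ties[-1])
    i, j = n, jbest
    matches = 0
    columns = 0
    while i > 0:
        sub = 0 if (j > 0 and qv[i - 1] == tv[j - 1]) else 1
        if j > 0 and D[i, j] == D[i - 1, j - 1] + sub:
            if sub == 0:
                matches += 1
                apos = (j - 1) if swapped else (i - 1)
                prof[apos] = 1
            columns += 1
            i -= 1
            j -= 1
        elif D[i, j] == D[i - 1, j] + 1:
            columns += 1
            i -= 1
        elif j > 0 and D[i, j] == D[i, j - 1] + 1:
            columns += 1
            j -= 1
        else:  # pragma: no cover - defensive
            break
    identity = 100.0 * matches / columns if columns else 0.0
    return {"identity": identity, "matches": matches, "columns": columns,
            "profile": prof}


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment (megablast-like scoring)
# ---------------------------------------------------------------------------

def smith_waterman(query: str, subject: str, match: int = 1,
                   mismatch: int = -2, gap: float = 2.5) -> dict | None:
    """Best local alignment under match/mismatch/linear-gap scoring.

    Scores are doubled internally so the default half-integer gap cost stays
    integral.  Returns None when the best score is <= 0, else a dict with the
    raw ``score`` and the usual tabular-hit statistics (1-based inclusive
    coordinates on query and subject).
    """
    n, m = len(query), len(subject)
    if n == 0 or m == 0:
        return None
    qv, sv = _as_bytes(query), _as_bytes(subject)
    ma, mi, g = 2 * match, 2 * mismatch, int(round(2 * gap))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    jcol = np.arange(1, m + 1) * g
    for i in range(1, n + 1):
        s = np.where(sv == qv[i - 1], ma, mi).astype(np.int32)
        cand = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - g)
        cand = np.maximum(cand, 0)
        # cur[j] = max(cand[j-1], cur[j-1] - g), left-to-right
        t = np.maximum.accumulate(cand + jcol)
        H[i, 1:] = np.maximum(t - jcol, 0)
    best = int(H.max())
    if best <= 0:
        return None
    bi, bj = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(bi), int(bj)
    matches = mismatches = gapopens = aln_len = 0
    in_gap = False
    qend, send = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        s = ma if qv[i - 1] == sv[j - 1] else mi
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == ma:
                matches += 1
            else:
                mismatches += 1
            aln_len += 1
            in_gap = False
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - g:
            if not in_gap:
                gapopens += 1
                in_gap = True
            aln_len += 1
            i -= 1
        elif H[i, j] == H[i, j - 1] - g:
            if not in_gap:
                gapopens += 1
                in_gap = True
            aln_len += 1
            j -= 1
        else:  # pragma: no cover - defensive
            break
    return {
        "score": best / 2.0,
        "matches": matches,
        "mismatches": mismatches,
        "gapopens": gapopens,
        "aln_len": aln_len,
        "qstart": i + 1, "qend": qend,
        "sstart": j + 1, "send": send,
    }


def bitscore(raw_score: float, lam: float = 1.28, k: float = 0.46) -> float:
    """Normalized bit score from a raw alignment score (Karlin-Altschul)."""
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def evalue(bits: float, query_len: int, db_len: int) -> float:
    """Expected chance hits: m * n * 2^-bitscore."""
    return float(query_len) * float(db_len) * math.pow(2.0, -bits)
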