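"""Independent brute-force reference implementations used as test oracles.

Deliberately written in the plainest possible style (quadratic DP tables,
explicit loops, literal rule transcriptions) with no shared code paths with
the package internals.
"""

import math

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def base_eq(a, b):
    return bool(IUPAC.get(a, {a}) & IUPAC.get(b, {b}))


def anchored_edit_distance(pattern, text):
    """Min unit-cost edit distance aligning the full pattern at the start
    of ``text``, the pattern's end free in the text (full quadratic DP)."""
    n, m = len(pattern), len(text)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i
    for j in range(1, m + 1):
        D[0][j] = j  # anchored: skipping text at the start costs
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if base_eq(pattern[i - 1], text[j - 1]) else 1
            D[i][j] = min(D[i - 1][j - 1] + cost, D[i - 1][j] + 1,
                          D[i][j - 1] + 1)
    return min(D[n])


def brute_match_primer(primer, read, error_rate, min_overlap):
    """(accepted, errors, span) under the anchored-with-truncation rule:
    the full primer within its edit budget, else the longest primer suffix
    (>= min_overlap) present exactly at the read start."""
    window = read[: len(primer) * 2 + 4]
    d = anchored_edit_distance(primer, window)
    if d <= math.floor(error_rate * len(primer)):
        return True, d, len(primer)
    for span in range(min(len(primer) - 1, len(read)), min_overlap - 1, -1):
        suffix = primer[len(primer) - span:]
        if len(read) >= span and all(
                base_eq(a, b) for a, b in zip(suffix, read[:span])):
            return True, 0, span
    return False, None, None


def brute_window_trim_length(quals, window, step, trim_q):
    """Length the read keeps under the sliding-window rule."""
    n = len(quals)
    off = 0
    while off < n:
        chunk = quals[off: off + window]
        if sum(chunk) / len(chunk) < trim_q:
            return off
        off += step
    return n


def brute_fraction_keep(quals, trim_q, frac):
    if len(quals) == 0:
        return False
    good = sum(1 for q in quals if q >= trim_q)
    return good / len(quals) >= frac - 1e-9


def brute_consensus_rank(hit_rows, species_to_genus, genus_to_family,
                         top_required=3):
    """Literal transcription of the interpretation guideline over a
    species/genus/family toy taxonomy.

    ``hit_rows``: list of (species, bitscore), any order.  Returns
    (rank, name).
    """
    if not hit_rows:
        return ("unassigned", "")
    rows = sorted(hit_rows, key=lambda r: -r[1])
    best = rows[0][1]
    tied = [r for r in rows if r[1] == best]
    k = len(tied) if len(tied) > top_required else top_required
    top = rows[:k]
    species = {r[0] for r in top}
    if len(species) == 1 and len(top) >= top_required:
        return ("species", top[0][0])
    genera = {species_to_genus[s] for s in species}
    if len(genera) == 1:
        return ("genus", genera.pop())
    families = {genus_to_family[g] for g in genera}
    if len(families) == 1:
        return ("family", families.pop())
    return ("unassigned", "")
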