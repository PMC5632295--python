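"""Amplicon-mixture simulator.

Builds a self-contained toy reference world (per-species template inserts
for each of the 12 panel loci, a matching reference FASTA with three
accession variants per species and locus, a taxonomy table and a CITES
listing table) and simulates paired-end Illumina reads from mixture
specifications: dry-mass fractions are mapped linearly to read fractions,
split uniformly across the loci a species amplifies (animal loci for
animals, plant loci for plants); each fragment is the locus-specific
primers plus insert flanked by the Illumina overhang adapters; mates of
fixed length are sampled from both fragment ends, with per-cycle quality
decay, uniform substitution errors carrying low quality values, and
optional single-crossover chimeric templates.

Everything is a pure function of the seed: read allocation uses
largest-remainder apportionment rather than multinomial draws, so mixture
fractions are honoured exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from ._align import IUPAC_SETS, revcomp
from .formats import (CitesEntry, Marker, NucRead, RefRecord, Taxonomy,
                      TaxonNode, FWD_OVERHANG, REV_OVERHANG,
                      load_marker_panel, write_acc2taxid, write_cites_table,
                      write_fasta, write_fastq, write_taxonomy)

logger = logging.getLogger(__name__)

ANIMAL_MARKERS = ("16S", "mini-16S", "COI", "mini-COI", "cyt b", "mini-cyt b")
PLANT_MARKERS = ("matK", "rbcL", "mini-rbcL", "trnL-UAA", "trnL-P6", "ITS2")

#: template insert lengths (nt, between primers) chosen inside each locus's
#: expected amplicon range; loci whose fragments exceed 2x300 deliberately
#: stay unmerged so both the pseudo-read and the unmerged-mate paths carry
#: signal.
INSERT_LEN = {
    "16S": 460, "mini-16S": 216, "COI": 597, "mini-COI": 261,
    "cyt b": 696, "mini-cyt b": 307,
    "matK": 700, "rbcL": 608, "mini-rbcL": 140, "trnL-UAA": 725,
    "trnL-P6": 80, "ITS2": 250,
}

#: (name, kingdom, genus, family, order, synonyms, congener_of)
_SPECIES_TABLE = [
    ("Bos taurus", "animal", "Bos", "Bovidae", "Artiodactyla", [], None),
    ("Bos indicus", "animal", "Bos", "Bovidae", "Artiodactyla", [],
     "Bos taurus"),
    ("Gallus gallus", "animal", "Gallus", "Phasianidae", "Galliformes",
     [], None),
    ("Gallus sonneratii", "animal", "Gallus", "Phasianidae", "Galliformes",
     [], "Gallus gallus"),
    ("Anguilla anguilla", "animal", "Anguilla", "Anguillidae",
     "Anguilliformes", [], None),
    ("Crocodylus niloticus", "animal", "Crocodylus", "Crocodylidae",
     "Crocodylia", [], None),
    ("Pieris brassicae", "animal", "Pieris", "Pieridae", "Lepidoptera",
     [], None),
    ("Parapenaeopsis hardwickii", "animal", "Parapenaeopsis", "Penaeidae",
     "Decapoda", [], None),
    ("Lactuca sativa", "plant", "Lactuca", "Asteraceae", "Asterales",
     [], None),
    ("Echinocactus grusonii", "plant", "Echinocactus", "Cactaceae",
     "Caryophyllales", [], None),
    ("Euphorbia milii", "plant", "Euphorbia", "Euphorbiaceae",
     "Malpighiales", [], None),
    ("Euphorbia lathyris", "plant", "Euphorbia", "Euphorbiaceae",
     "Malpighiales", [], "Euphorbia milii"),
    ("Aloe variegata", "plant", "Aloe", "Asphodelaceae", "Asparagales",
     ["Gonialoe variegata"], None),
    ("Cycas revoluta", "plant", "Cycas", "Cycadaceae", "Cycadales",
     [], None),
    ("Dendrobium nobile", "plant", "Dendrobium", "Orchidaceae",
     "Asparagales", [], None),
]

#: local CITES listing (synthetic projection of the appendices relevant to
#: the toy species set; Aloe variegata is listed under its synonym to
#: exercise synonym matching).
_CITES_ROWS = [
    ("Anguilla anguilla", "species", "II"),
    ("Crocodylus niloticus", "species", "I"),
    ("Gonialoe variegata", "species", "II"),
    ("Euphorbia", "genus", "II"),
    ("Cycas", "genus", "II"),
    ("Dendrobium", "genus", "II"),
    ("Cactaceae", "family", "II"),
]

_CONGENER_DIVERGENCE = 0.05  # fraction of mutated positions, > the 3% floor

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FILLER = "ATCTCGTATGCCGTCTTCTGCTTG"  # post-fragment filler (downstream adapter)


def _instantiate(primer: str) -> str:
    """Pick the lexicographically first concrete base per IUPAC code."""
    return "".join(sorted(IUPAC_SETS[c])[0] for c in primer)


def apportion(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` items to ``weights``."""
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = float(sum(weights))
    if wsum <= 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    counts = [math.floor(q) for q in quotas]
    rem = total - sum(counts)
    order = sorted(range(len(weights)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Toy reference database
# ---------------------------------------------------------------------------

@dataclass
class ToyRefDB:
    """In-memory toy reference world; writable as plain-text tables."""

    refdb: list[RefRecord]
    acc2taxid: dict[str, int]
    taxonomy: Taxonomy
    cites: list[CitesEntry]
    templates: dict[str, dict[str, str]]  # species -> marker -> insert
    kingdom: dict[str, str]
    seed: int

    def markers_of(self, species: str) -> tuple[str, ...]:
        return ANIMAL_MARKERS if self.kingdom[species] == "animal" \
            else PLANT_MARKERS

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "refdb.fasta",
            "acc2taxid": out / "acc2taxid.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "cites": out / "cites.tsv",
        }
        write_fasta(((r.accession, r.seq) for r in self.refdb), paths["fasta"])
        write_acc2taxid(self.acc2taxid, paths["acc2taxid"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        write_cites_table(self.cites, paths["cites"])
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return bytes(arr).decode()


def build_toy_refdb(seed: int, variants_per_species: int = 3) -> ToyRefDB:
    """Deterministically build the toy reference world for a seed.

    Per species and locus: one template insert (congeners derive from their
    parent species at 5% divergence, comfortably past the 3% floor) and
    ``variants_per_species`` reference accessions carrying 0, 1 and 2
    substitutions relative to the template, emulating the redundancy of
    public reference collections that the 3-top-hit species rule leans on.
    """
    rng = np.random.default_rng(seed)
    templates: dict[str, dict[str, str]] = {}
    kingdom: dict[str, str] = {}
    for name, kd, *_rest in _SPECIES_TABLE:
        kingdom[name] = kd
    for name, kd, _g, _f, _o, _syn, parent in _SPECIES_TABLE:
        markers = ANIMAL_MARKERS if kd == "animal" else PLANT_MARKERS
        templates[name] = {}
        for mk in markers:
            if parent is None:
                templates[name][mk] = _random_seq(rng, INSERT_LEN[mk])
            else:
                base = templates[parent][mk]
                n_sub = math.ceil(_CONGENER_DIVERGENCE * len(base))
                templates[name][mk] = _mutate(rng, base, n_sub)

    # taxonomy tree
    nodes = [TaxonNode(1, "root", "other", 1)]
    next_id = 2
    index: dict[tuple[str, str], int] = {}

    def _node(name: str, rank: str, parent: int) -> int:
        nonlocal next_id
        key = (name, rank)
        if key not in index:
            index[key] = next_id
            nodes.append(TaxonNode(next_id, name, rank, parent))
            next_id += 1
        return index[key]

    species_taxid: dict[str, int] = {}
    for name, _kd, genus, family, order, syns, _p in _SPECIES_TABLE:
        o = _node(order, "order", 1)
        f = _node(family, "family", o)
        g = _node(genus, "genus", f)
        s = _node(name, "species", g)
        nodes[s - 1].synonyms = list(syns)
        species_taxid[name] = s
    taxonomy = Taxonomy(nodes)

    refdb: list[RefRecord] = []
    acc2taxid: dict[str, int] = {}
    counter = 1
    for name, _kd, *_rest in _SPECIES_TABLE:
        for mk in templates[name]:
            tmpl = templates[name][mk]
            # non-zero variants carry ~0.2% substitutions (>= 1), staying
            # comfortably inside the 98% identity hit filter at every locus
            n_sub = max(1, round(0.002 * len(tmpl)))
            for v in range(variants_per_species):
                seq = tmpl if v == 0 else _mutate(rng, tmpl, n_sub)
                acc = f"TRD{counter:05d}"
                counter += 1
                refdb.append(RefRecord(acc, seq, species_taxid[name]))
                acc2taxid[acc] = species_taxid[name]

    cites = [CitesEntry(*row) for row in _CITES_ROWS]
    return ToyRefDB(refdb, acc2taxid, taxonomy, cites, templates, kingdom,
                    seed)


# ---------------------------------------------------------------------------
# Mixture specification and simulation
# ---------------------------------------------------------------------------

@dataclass
class Component:
    species: str
    mass_frac: float
    templates: dict[str, str]  # marker -> insert


@dataclass
class MixtureSpec:
    components: list[Component]
    n_read_pairs: int
    seed: int
    read_len: int = 300
    quality_profile: str = "typical"  # clean | typical | harsh
    sub_error_rate: float = 0.005
    chimera_rate: float = 0.01
    contaminant: Optional[tuple[str, float]] = None

    def validate(self) -> None:
        if self.n_read_pairs <= 0:
            raise ValueError("n_read_pairs must be positive")
        if any(c.mass_frac < 0 for c in self.components):
            raise ValueError("mass fractions must be non-negative")
        total = sum(c.mass_frac for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, expected 1")
        if self.quality_profile not in _PROFILE_END_Q:
            raise ValueError(
                f"unknown quality profile {self.quality_profile!r}")


def mixture_from_refdb(refdb: ToyRefDB, fractions: list[tuple[str, float]],
                       n_read_pairs: int, seed: int, **kw) -> MixtureSpec:
    comps = []
    for species, frac in fractions:
        if species not in refdb.templates:
            raise KeyError(f"species {species!r} not in reference database")
        comps.append(Component(species, frac, dict(refdb.templates[species])))
    spec = MixtureSpec(comps, n_read_pairs, seed, **kw)
    if spec.contaminant is not None:
        name, frac = spec.contaminant
        scale = 1.0 - frac
        for c in spec.components:
            c.mass_frac *= scale
        spec.components.append(
            Component(name, frac, dict(refdb.templates[name])))
    spec.validate()
    return spec


def em11_fractions() -> list[tuple[str, float]]:
    """The 10-component experimental-mixture design with two dominant
    ingredients (46% each) and eight minor ones at 1% dry mass."""
    return [
        ("Bos taurus", 0.46),
        ("Lactuca sativa", 0.46),
        ("Parapenaeopsis hardwickii", 0.01),
        ("Anguilla anguilla", 0.01),
        ("Gallus gallus", 0.01),
        ("Pieris brassicae", 0.01),
        ("Echinocactus grusonii", 0.01),
        ("Euphorbia milii", 0.01),
        ("Aloe variegata", 0.01),
        ("Cycas revoluta", 0.01),
    ]


# per-cycle mean quality: logistic decay from Q37 to the profile endpoint
_PROFILE_END_Q = {"clean": 35.0, "typical": 28.0, "harsh": 18.0}
_PROFILE_NOISE_SD = {"clean": 0.0, "typical": 2.0, "harsh": 2.5}
_START_Q = 37.0


def quality_profile_means(profile: str, read_len: int) -> np.ndarray:
    end_q = _PROFILE_END_Q[profile]
    c = np.arange(read_len, dtype=np.float64)
    mid = 0.6 * read_len
    scale = read_len / 8.0
    return end_q + (_START_Q - end_q) / (1.0 + np.exp((c - mid) / scale))


def _primer_pair(panel: dict[str, Marker], marker: str) -> tuple[str, str]:
    m = panel[marker]
    return _instantiate(m.fwd_primers[0]), _instantiate(m.rev_primers[0])


def _fragment(fwd_primer: str, insert: str, rev_primer: str) -> str:
    return (FWD_OVERHANG + fwd_primer + insert + revcomp(rev_primer)
            + revcomp(REV_OVERHANG))


def _pad(seq: str, length: int) -> str:
    while len(seq) < length:
        seq += _FILLER
    return seq[:length]


def simulate_mixture(spec: MixtureSpec, out_dir) -> dict[str, Path]:
    """Simulate paired FASTQ files plus a per-read truth table.

    Returns paths: r1, r2, truth.  Fully deterministic at a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    panel = {m.name: m for m in load_marker_panel()}
    L = spec.read_len
    means = quality_profile_means(spec.quality_profile, L)
    noise_sd = _PROFILE_NOISE_SD[spec.quality_profile]

    # --- read allocation -------------------------------------------------
    per_comp = apportion(spec.n_read_pairs,
                         [c.mass_frac for c in spec.components])
    # (species, marker) -> pairs
    alloc: list[tuple[Component, str, int]] = []
    marker_totals: dict[str, int] = {}
    for comp, n_pairs in zip(spec.components, per_comp):
        markers = [mk for mk in INSERT_LEN if mk in comp.templates]
        missing = [mk for mk in ANIMAL_MARKERS + PLANT_MARKERS
                   if mk not in comp.templates]
        if missing:
            logger.info("simulate: %s lacks template(s) for %s "
                        "(amplification dropout)", comp.species, missing)
        per_marker = apportion(n_pairs, [1.0] * len(markers))
        for mk, n in zip(markers, per_marker):
            if n > 0:
                alloc.append((comp, mk, n))
                marker_totals[mk] = marker_totals.get(mk, 0) + n

    # --- chimeric templates ----------------------------------------------
    chim_alloc: list[tuple[str, str, str, int]] = []  # species-tag, marker, seq
    if spec.chimera_rate > 0:
        by_marker: dict[str, list[tuple[Component, str, int]]] = {}
        for item in alloc:
            by_marker.setdefault(item[1], []).append(item)
        for mk in sorted(by_marker):
            items = by_marker[mk]
            n_chim = round(spec.chimera_rate * marker_totals[mk])
            if n_chim < 1 or len(items) < 2:
                continue
            items_sorted = sorted(items, key=lambda it: (-it[2],
                                                         it[0].species))
            (ca, _, na), (cb, _, _nb) = items_sorted[0], items_sorted[1]
            ta, tb = ca.templates[mk], cb.templates[mk]
            chim_seq = ta[: len(ta) // 2] + tb[len(tb) // 2:]
            n_chim = min(n_chim, na - 1)
            if n_chim < 1:
                continue
            # chimeric pairs replace pairs of the most abundant parent
            for i, item in enumerate(alloc):
                if item[0] is ca and item[1] == mk:
                    alloc[i] = (ca, mk, item[2] - n_chim)
                    break
            chim_alloc.append((f"chimera:{ca.species}+{cb.species}", mk,
                               chim_seq, n_chim))

    # --- per-block read synthesis ----------------------------------------
    seqs1: list[str] = []
    seqs2: list[str] = []
    meta: list[tuple[str, str, int]] = []
    quals1: list[np.ndarray] = []
    quals2: list[np.ndarray] = []

    def _emit(species: str, marker: str, insert: str, n: int, chim: int):
        fp, rp = _primer_pair(panel, marker)
        frag = _fragment(fp, insert, rp)
        r1_t = _pad(frag, L)
        r2_t = _pad(revcomp(frag), L)
        for template, sink, qsink in ((r1_t, seqs1, quals1),
                                      (r2_t, seqs2, quals2)):
            base = np.frombuffer(template.encode(), dtype=np.uint8)
            block = np.tile(base, (n, 1))
            if noise_sd > 0:
                q = means + rng.normal(0.0, noise_sd, size=(n, L))
            else:
                q = np.tile(means, (n, 1))
            q = np.clip(np.rint(q), 2, 41).astype(np.int16)
            if spec.sub_error_rate > 0:
                err = rng.random((n, L)) < spec.sub_error_rate
                n_err = int(err.sum())
                if n_err:
                    # substitute to one of the three other bases
                    idx = np.searchsorted(_BASES, block[err])
                    shift = rng.integers(1, 4, size=n_err)
                    block[err] = _BASES[(idx + shift) % 4]
                    q[err] = rng.integers(3, 15, size=n_err)
            for row in range(n):
                sink.append(bytes(block[row]).decode())
                qsink.append(q[row])
        meta.extend([(species, marker, chim)] * n)

    for comp, mk, n in alloc:
        if n > 0:
            _emit(comp.species, mk, comp.templates[mk], n, 0)
    for tag, mk, seq, n in chim_alloc:
        _emit(tag, mk, seq, n, 1)

    # --- shuffle, name, write --------------------------------------------
    n_total = len(meta)
    order = rng.permutation(n_total)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"r1": out / "reads_R1.fastq", "r2": out / "reads_R2.fastq",
             "truth": out / "truth.tsv"}
    reads1, reads2, truth_rows = [], [], []
    for new_idx, old_idx in enumerate(order):
        rid = f"sim_{new_idx:07d}"
        reads1.append(NucRead(rid, seqs1[old_idx],
                              [int(x) for x in quals1[old_idx]]))
        reads2.append(NucRead(rid, seqs2[old_idx],
                              [int(x) for x in quals2[old_idx]]))
        sp, mk, chim = meta[old_idx]
        truth_rows.append(f"{rid}\t{sp}\t{mk}\t{chim}")
    write_fastq(reads1, paths["r1"])
    write_fastq(reads2, paths["r2"])
    paths["truth"].write_text("#read_id\tspecies\tmarker\tchimera\n"
                              + "\n".join(truth_rows)
                              + ("\n" if truth_rows else ""))
    return paths


def load_truth(path) -> list[dict]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rid, sp, mk, chim = line.split("\t")
        rows.append({"read_id": rid, "species": sp, "marker": mk,
                     "chimera": chim == "1"})
    return rows
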