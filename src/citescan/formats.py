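"""Domain types and readers/writers for every external representation.

Covers FASTQ (Phred+33) and FASTA, the marker-panel table, taxonomy and
accession-to-taxid tables, the CITES listing table, the 13-column tabular
hit format and the final report.  Sequence I/O is delegated to Biopython
behind thin wrappers that enforce this package's invariants (quality range,
IUPAC alphabet, record indexing in error messages).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._align import IUPAC_SETS

PathLike = Union[str, Path]

IUPAC_CODES = frozenset(IUPAC_SETS) | {"U"}

#: Illumina overhang adapters flanking every locus-specific primer in the
#: packaged panel; adapter trimming removes these tails before primer
#: matching, so the panel stores locus-specific parts only.
FWD_OVERHANG = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
REV_OVERHANG = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

MAX_PHRED = 41


class FormatError(ValueError):
    """Malformed external file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NucRead:
    """A nucleotide sequence with per-base Phred qualities."""

    read_id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, stop: Optional[int] = None) -> "NucRead":
        return NucRead(self.read_id, self.seq[start:stop], self.quals[start:stop])


@dataclass
class Marker:
    """One barcode primer set (locus-specific parts, overhang stripped)."""

    name: str
    fwd_primers: list[str]
    rev_primers: list[str]
    min_barcode_len: int
    expected_len: tuple[int, int]
    pool_name: str = ""

    def __post_init__(self) -> None:
        if not self.pool_name:
            self.pool_name = self.name
        if not self.fwd_primers or not self.rev_primers:
            raise ValueError(f"marker {self.name}: primers must be non-empty")


@dataclass
class RefRecord:
    """A reference sequence with its taxonomy id (local database record)."""

    accession: str
    seq: str
    taxid: int


@dataclass
class TaxonNode:
    taxid: int
    name: str
    rank: str  # species | genus | family | order | other
    parent_taxid: int
    synonyms: list[str] = field(default_factory=list)


@dataclass
class CitesEntry:
    """One row of the local CITES listing table."""

    listed_name: str
    listed_rank: str  # species | genus | family | order
    appendix: str     # I | II | III

    def __post_init__(self) -> None:
        if self.appendix not in ("I", "II", "III"):
            raise FormatError(f"unknown CITES appendix {self.appendix!r}")
        if self.listed_rank not in ("species", "genus", "family", "order"):
            raise FormatError(f"unknown CITES rank {self.listed_rank!r}")


@dataclass
class PipelineParams:
    """Every tunable of the pipeline with its default value.

    Defaults are the recommended settings established for the method:
    Q20 trimming with 95% of bases >= Q20, 0.2% OTU abundance threshold,
    98% identity OTU radius and hit filters of 98% identity / 90% query
    coverage with a species call requiring 3 concordant top hits.
    """

    adapter_5p: str = "TGTGTATAAGAGACAG"
    adapter_3p: str = "CTGTCTCTTATACACA"
    min_read_len: int = 10
    trim_q: int = 20
    window: int = 15
    step: int = 5
    frac_q20: float = 0.95
    merge_min_overlap: int = 16
    merge_max_mismatch_frac: float = 0.05
    adapter_error_rate: float = 0.1
    primer_error_rate: float = 0.2
    primer_min_overlap: int = 6
    derep_min_size: int = 4
    otu_radius_pct: float = 2.0
    otu_abundance_frac: float = 0.002
    default_min_barcode_len: int = 200
    chimera_min_model_identity: float = 99.0
    chimera_min_segment: int = 16
    chimera_margin: float = 2.0
    aln_match: int = 1
    aln_mismatch: int = -2
    aln_gap: float = 2.5
    aln_lambda: float = 1.28
    aln_k: float = 0.46
    search_word_size: int = 16
    hit_evalue_max: float = 0.001
    hit_max_targets: int = 20
    hit_min_identity_pct: float = 98.0
    hit_min_query_cov_pct: float = 90.0
    top_hits_required: int = 3
    count_both_unmerged_mates: bool = True

    def validate(self) -> None:
        for name in ("frac_q20", "otu_abundance_frac", "primer_error_rate",
                     "adapter_error_rate", "merge_max_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_read_len", "window", "step", "primer_min_overlap",
                     "derep_min_size", "default_min_barcode_len",
                     "hit_max_targets", "top_hits_required",
                     "merge_min_overlap", "search_word_size"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name}={v} must be a positive integer")

    @classmethod
    def from_config(cls, path: PathLike | None = None,
                    overrides: dict | None = None) -> "PipelineParams":
        """Build params from a flat key-value YAML file plus overrides.

        Precedence: override > config file > default.
        """
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise FormatError(f"config {path}: expected a flat mapping")
            values.update(data)
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise FormatError(f"unknown parameter(s): {sorted(unknown)}")
        params = cls(**values)
        params.validate()
        return params


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def parse_fastq(source: Union[PathLike, IO[str]]) -> Iterator[NucRead]:
    """Yield NucReads from 4-line FASTQ, qualities decoded as Phred+33."""
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    try:
        idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise FormatError(
                        f"FASTQ record {idx}: sequence/quality length mismatch")
                quals = [ord(c) - 33 for c in qual]
                bad = [q for q in quals if q < 0 or q > 60]
                if bad:
                    raise FormatError(
                        f"FASTQ record {idx}: quality out of range")
                seq = seq.upper()
                if not set(seq) <= IUPAC_CODES:
                    raise FormatError(
                        f"FASTQ record {idx}: non-IUPAC character in sequence")
                yield NucRead(title.split()[0], seq, quals)
                idx += 1
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"FASTQ record {idx}: {exc}") from exc
    finally:
        if own:
            fh.close()


def write_fastq(reads: Iterable[NucRead], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def parse_fasta(source: PathLike) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from FASTA."""
    from Bio import SeqIO
    for rec in SeqIO.parse(str(source), "fasta"):
        yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

def _check_primer(p: str, marker: str) -> str:
    p = p.upper()
    for ch in p:
        if ch == "I":
            continue  # inosine, normalized below
        if ch not in IUPAC_CODES:
            raise FormatError(
                f"marker {marker}: primer {p} contains non-IUPAC character "
                f"{ch!r}")
    # inosine pairs promiscuously; treat as N
    return p.replace("I", "N")


def load_marker_panel(path: PathLike | None = None) -> list[Marker]:
    """Load a marker-panel TSV; with no path, the packaged 12-marker panel.

    Columns: name, pool, fwd_primers (';'-separated), rev_primers, min_len,
    len_lo, len_hi.  Primers are locus-specific parts with the Illumina
    overhangs already stripped.
    """
    if path is None:
        res = importlib.resources.files("citescan").joinpath(
            "data/marker_panel.tsv")
        text = res.read_text()
    else:
        text = Path(path).read_text()
    markers: list[Marker] = []
    seen: set[str] = set()
    for ln, line in enumerate(text.splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 7:
            raise FormatError(f"marker panel line {ln + 1}: expected 7 columns")
        name, pool, fwd, rev, min_len, lo, hi = parts
        if name in seen:
            raise FormatError(f"duplicate marker name {name!r}")
        seen.add(name)
        markers.append(Marker(
            name=name,
            pool_name=pool,
            fwd_primers=[_check_primer(p, name) for p in fwd.split(";") if p],
            rev_primers=[_check_primer(p, name) for p in rev.split(";") if p],
            min_barcode_len=int(min_len),
            expected_len=(int(lo), int(hi)),
        ))
    return markers


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANK_ORDER = {"species": 0, "genus": 1, "family": 2, "order": 3, "other": 4}


class Taxonomy:
    """Taxonomy tree with name/synonym lookup and lineage resolution."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for n in nodes:
            if n.taxid in self.nodes:
                raise FormatError(f"duplicate taxid {n.taxid}")
            self.nodes[n.taxid] = n
        self._validate()
        self._by_name: dict[tuple[str, str], int] = {}
        for n in self.nodes.values():
            self._by_name[(n.name, n.rank)] = n.taxid

    def _validate(self) -> None:
        for n in self.nodes.values():
            seen = set()
            t = n.taxid
            while True:
                if t in seen:
                    raise FormatError(f"taxonomy cycle at taxid {t}")
                seen.add(t)
                node = self.nodes.get(t)
                if node is None:
                    raise FormatError(
                        f"taxid {t} (ancestor of {n.taxid}) missing from table")
                if node.parent_taxid == t:
                    break  # root
                t = node.parent_taxid

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def node(self, taxid: int) -> TaxonNode:
        return self.nodes[taxid]

    def lineage(self, taxid: int) -> dict[str, TaxonNode]:
        """Map rank -> node for every named rank on the path to the root."""
        out: dict[str, TaxonNode] = {}
        t = taxid
        while True:
            node = self.nodes[t]
            if node.rank not in out:
                out[node.rank] = node
            if node.parent_taxid == t:
                break
            t = node.parent_taxid
        return out

    def find(self, name: str, rank: str) -> Optional[int]:
        return self._by_name.get((name, rank))


def load_taxonomy(path: PathLike) -> Taxonomy:
    """Load taxonomy nodes TSV: taxid, parent, rank, name, synonyms(';')."""
    nodes = []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"taxonomy line {ln + 1}: expected >= 4 columns")
        taxid, parent, rank, name = parts[:4]
        syn = parts[4].split(";") if len(parts) > 4 and parts[4] else []
        if rank not in RANK_ORDER:
            rank = "other"
        nodes.append(TaxonNode(int(taxid), name, rank, int(parent),
                               [s.strip() for s in syn if s.strip()]))
    return Taxonomy(nodes)


def write_taxonomy(taxonomy: Taxonomy, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#taxid\tparent\trank\tname\tsynonyms\n")
        for t in sorted(taxonomy.nodes):
            n = taxonomy.nodes[t]
            fh.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\t"
                     f"{';'.join(n.synonyms)}\n")


def load_acc2taxid(path: PathLike) -> dict[str, int]:
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc, taxid = line.split("\t")[:2]
        out[acc] = int(taxid)
    return out


def write_acc2taxid(mapping: dict[str, int], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#accession\ttaxid\n")
        for acc in sorted(mapping):
            fh.write(f"{acc}\t{mapping[acc]}\n")


def load_refdb(fasta_path: PathLike, acc2taxid_path: PathLike,
               taxonomy: Taxonomy | None = None) -> list[RefRecord]:
    mapping = load_acc2taxid(acc2taxid_path)
    records = []
    for acc, seq in parse_fasta(fasta_path):
        if not seq:
            raise FormatError(f"reference {acc}: empty sequence")
        if acc not in mapping:
            raise FormatError(f"reference {acc}: no taxid mapping")
        taxid = mapping[acc]
        if taxonomy is not None and taxid not in taxonomy:
            raise FormatError(f"reference {acc}: taxid {taxid} not in taxonomy")
        records.append(RefRecord(acc, seq, taxid))
    return records


# ---------------------------------------------------------------------------
# CITES table
# ---------------------------------------------------------------------------

def load_cites_table(path: PathLike) -> list[CitesEntry]:
    """Load CITES listing TSV: name, rank, appendix; unique per (name, rank)."""
    entries = []
    seen = set()
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"CITES line {ln + 1}: expected 3 columns")
        name, rank, appendix = (p.strip() for p in parts[:3])
        key = (name, rank)
        if key in seen:
            raise FormatError(f"duplicate CITES entry {key}")
        seen.add(key)
        entries.append(CitesEntry(name, rank, appendix))
    return entries


def write_cites_table(entries: Iterable[CitesEntry], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#name\trank\tappendix\n")
        for e in entries:
            fh.write(f"{e.listed_name}\t{e.listed_rank}\t{e.appendix}\n")


# ---------------------------------------------------------------------------
# Tabular hit format (12 standard columns + taxid)
# ---------------------------------------------------------------------------

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore",
               "taxid")


def write_hits_table(hits, path: PathLike) -> None:
    """Write Hits (taxassign.Hit) in 13-column tabular form."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.accession, f"{h.pident:.3f}", str(h.aln_len),
                str(h.mismatches), str(h.gapopens), str(h.qstart),
                str(h.qend), str(h.sstart), str(h.send),
                f"{h.evalue:.3e}", f"{h.bitscore:.6g}", str(h.taxid),
            ]) + "\n")


def read_hits_table(path: PathLike):
    """Read a 13-column tabular hit file back into Hit objects."""
    from .taxassign import Hit
    hits = []
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        p = line.split("\t")
        if len(p) != 13:
            raise FormatError(f"hit table line {ln + 1}: expected 13 columns")
        hits.append(Hit(
            query_id=p[0], accession=p[1], pident=float(p[2]),
            aln_len=int(p[3]), mismatches=int(p[4]), gapopens=int(p[5]),
            qstart=int(p[6]), qend=int(p[7]), sstart=int(p[8]),
            send=int(p[9]), evalue=float(p[10]), bitscore=float(p[11]),
            taxid=int(p[12])))
    return hits


# ---------------------------------------------------------------------------
# Final report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "otu_id", "marker_pool", "otu_size", "abundance_frac",
    "accession", "pident", "query_cov_pct", "bitscore", "evalue",
    "scientific_name", "synonym_names",
    "assigned_rank", "assigned_name",
    "cites_appendix", "cites_listed_name", "cites_listed_rank",
)


def write_report(rows: Iterable[dict], path: PathLike) -> None:
    """Write the final TSV report: one row per retained hit per OTU.

    ``rows`` are dicts keyed by REPORT_COLUMNS (missing keys are emitted
    empty); produced by the pipeline from assignments and CITES calls.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in REPORT_COLUMNS)
                     + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        if v != 0 and (abs(v) < 1e-3 or abs(v) >= 1e6):
            return f"{v:.3e}"
        return f"{v:.4g}"
    return str(v)


def read_report(path: PathLike) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty report")
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        out.append(dict(zip(header, line.split("\t"))))
    return out
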