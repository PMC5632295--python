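# Methods

This note documents the models and procedures implemented in `citescan`,
the parameters that matter, what the built-in simulator does and does not
emulate, and the numerical choices behind the defaults.

## Pipeline model

The pipeline treats a paired-end amplicon library as a mixture of PCR
products from a 12-locus barcode panel amplifying animal (16S, mini-16S,
COI, mini-COI, cyt b, mini-cyt b) and plant (matK, rbcL, mini-rbcL,
trnL-UAA, trnL-P6, ITS2) templates. It is presence/absence oriented: the
goal is to support or refute the presence of taxa, with per-OTU read
counts reported as evidence, not as quantitative composition.

Every stage is a pure function of its inputs and parameters. There is no
randomness anywhere downstream of the FASTQ files, so a run is reproducible
byte for byte.

### Pre-processing

* **Adapter trimming.** The Illumina overhang substrings
  `TGTGTATAAGAGACAG` (5′) and `CTGTCTCTTATACACA` (3′) are located
  error-tolerantly (edit distance ≤ 10% of the adapter length; partial
  terminal occurrences honoured down to 3 nt). Everything up to and
  including a 5′ occurrence, and a 3′ occurrence plus everything after it,
  is removed. Reads ≤ `min_read_len` (10 nt) are dropped.
* **Merging.** The reverse mate is reverse-complemented and the ungapped
  suffix/prefix overlap of length ≥ 16 minimizing the mismatch fraction is
  chosen; the pair merges when that fraction is ≤ 0.05. In the overlap,
  agreeing bases keep the higher quality; disagreements take the
  higher-quality base with quality |q₁ − q₂| — residual quality after the
  two observations effectively cancel. The 16 / 0.05 merge constants are
  not dictated by the method itself; they emulate common merger defaults
  and are config-overridable. Exact-16-mer seeding proposes candidate
  overlaps before an exhaustive scan; the exhaustive scan is the fallback,
  so seeding is a pure speed-up for error-free overlaps.
* **Quality trimming.** Windows of 15 nt at offsets 0, 5, 10, … (clipped
  at the read end; a read shorter than one window is a single whole-read
  window): the first window with mean quality < `trim_q` (20) truncates
  the read at that window's start. The windowing arithmetic (fixed
  offsets, truncate at the failing window's start) is pinned here because
  sliding-window trimmers differ in detail.
* **Fraction filter.** Keep iff (bases with Q ≥ `trim_q`) / length ≥
  `frac_q20` (0.95), boundary inclusive (a 100-nt read with exactly 95
  such bases is kept). Comparisons use an absolute epsilon of 1e-9 so the
  inclusive boundary survives binary floating point.
* Merged, unmerged-forward and unmerged-reverse streams are
  quality-filtered separately, and both mates of an unmerged pair count as
  independent (pseudo-)reads downstream.

### Primer demultiplexing

A read is tested against each marker's forward primers as-is and reverse
primers directly (a reverse-strand read *starts* with a reverse primer);
matching is anchored at the read start, with unit-cost edit distance
(substitutions = indels = 1), degenerate IUPAC codes matching their base
set at zero cost, and a budget of `floor(0.2 × primer length)` errors.
Two design choices deviate from the most literal reading of per-marker,
first-match selection, both forced by observed behaviour:

* **Best match wins.** All full-length primer matches across the panel
  compete on error fraction (ties: longer span, then panel order, forward
  before reverse). The COI cocktail primers contain inosine (stored as N)
  and tolerate 5 errors at full length; tried in panel order with
  first-match-wins they capture cyt b and other loci wholesale. With
  competition, a read's own locus (0–1 errors) always outranks a foreign
  cocktail match. The panel-order tie-break preserves pooling semantics
  for the loci that share a primer (cyt b / mini-cyt b land in "cyt b",
  COI / mini-COI in "COI").
* **Truncated anchors are exact.** A read may begin mid-primer (when
  upstream trimming clipped into it); suffixes of the primer down to 6 nt
  are accepted, longest first, but only on an exact IUPAC-aware match.
  Granting short spans their own `floor(0.2 × span)` budget (1 error at
  6–9 nt) makes 20–30% of *random* sequence match some primer tail, which
  defeats the purpose of specific selection. Truncated anchors are only
  consulted when no full primer matches anywhere.

After 5′ trimming, the reverse complement of any opposite-orientation
primer of the *pool* is removed from the 3′ side with standard trimmer
semantics: a full occurrence anywhere cuts it and everything downstream
(read-through into adapter is removed with it); partial occurrences at the
very end are honoured down to 6 nt (exact). Reverse-strand reads are then
re-oriented. Reads ≤ 10 nt after trimming are discarded as unassigned.

### OTU construction

* **Prefix dereplication.** Identical sequences and exact prefixes of
  longer sequences collapse; the representative is the longest sequence
  (ties: higher count, then lexicographic). Groups below `derep_min_size`
  (4) are discarded — this is where most error-bearing reads exit, since a
  read with a sequencing error is usually unique. Prefix (not strict)
  dereplication matters because quality trimming truncates reads at
  variable 3′ offsets.
* **Identity definition.** Identity between two sequences is matches /
  alignment columns under a unit-cost global alignment in which only the
  *longer* sequence has free (and uncounted) terminal gaps. The shorter
  sequence aligns end to end: a read contained in a longer centroid scores
  on its full length, equal-length sequences get a plain global alignment,
  and unrelated sequences can never reach high identity through a chance
  micro-overlap (which a fully end-gap-free formulation permits).
* **Greedy clustering.** Uniques are processed in decreasing size
  (lexicographic tie-break, making clustering invariant to input order);
  a candidate joins the best centroid with identity ≥ 100 − `otu_radius_pct`
  (98%), else it is chimera-screened and, if clean, founds a new centroid.
* **Chimera model.** A candidate is chimeric iff two distinct existing
  centroids admit a single crossover position splitting it into segments
  of ≥ 16 nt such that the two-segment model reaches ≥ 99% identity to
  the candidate and beats the best single-centroid identity by ≥ 2
  points. Profiles are ungapped, in candidate coordinates: chimera
  formation by template switching preserves the coordinate frame when
  divergence is substitution-dominated, and the ungapped profile makes
  the prefix-sum decomposition over crossover positions exact. Gapped
  profiles were tried and rejected: optimal edit paths pick up chance
  matches in the unrelated half and can break single true-half positions,
  making the 99% threshold brittle. Multi-crossover chimeras and
  indel-shifted parents are out of scope of this model.
* **Thresholds.** OTUs are kept iff size / pool reads ≥
  `otu_abundance_frac` (0.2%, boundary inclusive — so a component at
  exactly the threshold is detectable) *and* centroid length ≥ the
  marker's floor (200 nt default; 140 / 100 / 10 nt for mini-rbcL / ITS2 /
  trnL-P6, loci whose amplicons are intrinsically short). The denominator
  is reads assigned to the pool, before dereplication. Abundance and
  length are applied jointly in one pass.

### Taxonomy prediction and CITES matching

* **Search.** Smith–Waterman local alignment with match +1, mismatch −2,
  linear gap 2.5 per column; bit score = (λS − ln K)/ln 2 with ungapped
  Karlin–Altschul parameters λ = 1.28, K = 0.46; E-value = m·n·2^(−bits)
  with m the query length and n the total database length. Up to 20
  targets at E ≤ 0.001, sorted by bit score (ties by accession). An exact
  16-mer word index preselects candidate references — the same idea as
  megablast's exact-seed heuristic (whose default word is even longer), so
  references sharing no 16-mer with the query are never aligned. An
  adapter for externally produced 13-column tabular hit files
  (`read_hits_table`) lets users substitute a production search engine.
* **Consensus rule.** The decisive set is the first k bit-score-sorted
  hits, k = max(3, size of the tie set at the maximum bit score); ties are
  detected on bit scores rounded to 2 decimals (the precision they are
  reported at). All decisive hits mapping to one species with at least 3
  hits → species call; otherwise the lowest rank on which the decisive
  set agrees (genus, family, order), else unassigned. Note the
  consequences: two hits of the same species give a *genus* call; a
  max-score tie between congeners gives a genus call regardless of how
  many lower hits agree.
* **CITES matching.** The assignment's lineage is resolved from the
  assigned rank upward; at each rank the taxon's name (plus, at species
  rank, its synonyms) is compared exact-string (whitespace-normalized)
  against the listing table entries of that rank. The most specific match
  wins; a species matched through a synonym is reported at level
  "synonym". No fuzzy name matching.

### Statistics

Per sample: `%QC` = surviving raw-read equivalents / raw reads, where a
merged pseudo-read represents both of its mates (so a perfectly merged,
perfectly clean library is 100%, and the figure is comparable to raw-read
accounting); `%assigned` = barcode-assigned (pseudo-)reads / QC
(pseudo-)reads (merged = 1 here, since assignment operates on
pseudo-reads); `%OTU` = reads in retained OTUs / assigned reads.
Percentages are reported rounded to 2 decimals.

## The simulator

`build_toy_refdb` constructs a deterministic toy reference world: 15
species (including three congeneric pairs at exactly 5% template
divergence, safely past the 3% separability floor) across 12 genera, 11
families and 10 orders, each with one random template insert per locus of
its kingdom and three reference accessions per (species, locus) — the
exact template plus two variants at ~0.2% substitutions (≥ 1), emulating
the redundancy of public collections that the 3-top-hit species rule
relies on. Insert lengths sit inside each locus's expected amplicon range;
loci whose fragments exceed 2 × 300 nt (COI, cyt b, matK, rbcL, trnL-UAA)
deliberately stay unmerged so both the pseudo-read and unmerged-mate
paths carry signal. A CITES table lists two species directly, one species
under its synonym, three genera and one family.

`simulate_mixture` maps dry-mass fractions linearly to read fractions
(no copy-number or amplification-bias model — the pipeline is
presence/absence oriented and no quantitative mass-to-reads relation is
assumed), splits each species' reads uniformly across the loci it has
templates for, and apportions read counts by largest remainder rather
than multinomial draws: the mixtures emulate pooling amplicons at fixed
concentrations, and exact apportionment makes threshold phenomenology
(e.g. a 0.15% component against a 0.2% threshold) a property of the
method rather than of sampling noise. Fragments are
overhang + primer + insert + reverse-complemented primer + overhang, with
a fixed downstream filler when shorter than the read length; mates of 300
nt are read from both ends. Quality follows a logistic per-cycle decay
from Q37 to 35 / 28 / 18 (clean / typical / harsh) with Gaussian per-base
noise (σ = 0 / 2 / 2.5); substitution errors are uniform per base at
`sub_error_rate` and carry low quality values (Q3–14), which is what
makes pair-merging corrective and the fraction filter informative.
Chimeras are generated as single-crossover templates between the two most
abundant components of a locus, at `chimera_rate` of that locus's reads,
replacing reads of the dominant parent; a per-read truth table records
species, locus and chimera status. A species missing a locus template is
skipped for that locus and logged, emulating PCR dropout.

Default study conditions (20,000 read pairs, typical profile, 0.5%
substitution error, 1% chimeras) reflect a down-scaled sample of the
platform this method targets; the scaling keeps per-component read counts
in proportion.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: indel sequencing errors and quality-binning
artifacts, amplification bias and locus-specific copy number, DNA
degradation of processed samples, cross-contamination between samples,
and real reference-database heterogeneity (misannotations, uneven
coverage, shared haplotypes between congeners). Species-level resolution
on real data is limited by the reference collection, not only by the
algorithm.

## Numerical choices and degenerate inputs

* All boundary comparisons on fractions use a 1e-9 absolute epsilon,
  inclusive on the stated side.
* Error budgets use `floor(rate × length)` throughout.
* Zero-length reads are dropped by the fraction filter; empty pools
  produce empty OTU sets; an empty hit list yields rank "unassigned";
  an empty CITES table yields no calls; zero raw reads produce zeroed
  percentages with a warning.
* Tie-breaks are fixed everywhere (sequence-lexicographic in
  dereplication and clustering, accession-lexicographic in hit sorting,
  panel order in demultiplexing), so every stage is order-independent and
  deterministic.
* `--threads` is accepted for interface compatibility but does not change
  results; all stages are single-threaded and deterministic.

## Problem sizes used in the test suite

The end-to-end checks run the 10-component mixture at 20,000 read pairs
(the full study-condition scale) and smaller 2,000–3,000-pair mixtures for
stage-level properties; oracle-equivalence checks use 1,000 random reads
and an exhaustive ~15,000-case consensus enumeration. These sizes were
chosen so the whole suite exercises every code path at realistic depth
while remaining comfortably runnable on one CPU.

## Known limitations

* The chimera screen is de novo against already-accepted centroids; a
  chimera processed before either parent becomes a centroid cannot be
  flagged (it then typically yields an unassigned OTU, since its identity
  to any reference stays far below the hit filters).
* The internal search engine emulates megablast's scoring but is not a
  bit-for-bit reproduction; database-snapshot-dependent results are out
  of scope by design, and external tabular hit files can be substituted.
* Synonym matching is exact-string; misspelled or reformatted names in a
  CITES export will not match.
* The order-level fallback is the last consensus rank; conflicts above
  order are reported as unassigned.
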