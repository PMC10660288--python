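# Methods

This note documents the conventions, algorithms and design choices behind
`fgharmonize`, and what the synthetic-data generator does and does not
emulate.

## Inputs and configuration

A project is described by a **minimal descriptions table** (MDT): a TSV with
one row per input file and required columns `track_id`, `datatype`
(`intervals` | `qtl` | `interactions`), `biosample_term`, `assay_type`,
`genome_build` (`GRCh37/hg19` or `GRCh38/hg38`, several spellings accepted),
`data_source`, `file_path`, `config_path`. `biosample_type`, `life_stage` and
`doi` are recognized optional columns; any further column is preserved in the
track-description metadata as `key=value` pairs in MDT column order. Relative
paths resolve against the MDT's directory. Validation reports *every* problem
in the batch at once, and any problem aborts before data processing starts
(fail-fast).

Each input file has a **file config**, a flat text format with one statement
per line (`#` comments):

```
delimiter = tab            # tab|comma|space|semicolon|pipe or a literal char
has_header = true
coordinate_base = 1        # 0 or 1
chrom_style = auto         # auto|bare|chr_prefixed (informational; parsing is auto)
passthrough = colA, colB   # unmapped input columns kept after standard fields
position -> pos            # input column (1-based index or header name) -> field
```

Defaults: tab, header present, 1-based, auto. Mapping an output field twice,
mapping one input column to two fields, or naming an unknown field is a
validation error (the error lists the valid fields for the datatype).
Required mappings per datatype: intervals `chrom,start,end`; QTL
`chrom, pos` (or `start`+`end`), `ref, alt, beta, pvalue, variant_id,
target_id`; interactions both anchors' `chrom/start/end`. A QTL record's
`tissue`, when unmapped, defaults to the MDT `biosample_term`.

The **controlled vocabulary** is a bundled, editable TSV
(`term → tissue_category → system_category`, 34 terms). Lookup is flat and
case-insensitive; unmatched terms degrade to `uncategorized` with a warning
rather than failing, so one unrecognized label cannot block a batch. No
ontology-graph reasoning is attempted.

## Standard (type-independent) steps

1. **Column mapping** into the fixed output layout; missing optional fields
   get the BED `.` sentinel; passthrough columns append after the standard
   fields in configured order. Rows shorter than the highest mapped column
   are rejected per-row with their line number.
2. **Chromosome normalization** to chr-prefixed names: `1 → chr1`,
   `MT/chrMT/M → chrM`, `x → chrX`; unknown contigs keep their spelling and
   gain the prefix. The function is idempotent.
3. **Coordinate conversion** to 0-based half-open: 1-based inclusive
   `(s, e) → (s−1, e)`; 0-based passes through; a single position becomes a
   1 bp interval. For QTLs given only a position, the footprint is
   `end = start + len(ref)`, so deletion records span their deleted bases.
4. **Sort, compress, index**: rows are sorted by the deterministic total
   order (chromosome lexicographic on normalized names — the tabix
   convention, not karyotype order — then start, end, then the full line as
   tie-break, so duplicate rows are retained adjacently), bgzip-compressed
   and tabix-indexed (`bed` preset). An empty record set still produces a
   valid, indexed, empty track.

Interval scores are clamped to the BED range [0, 1000] with a warning.
Rejected rows go to `<track_id>.rejects` (line, reason, raw text);
`accepted + rejected = input rows` always holds.

## QTL normalization

The variant reference is an abstract lookup contract: a site table keyed on
`(chrom, start, end)` giving `(rsid, ref, alternate alleles)` — in
production a dbSNP-derived table; in the tests a generated one — plus random
access to the genome FASTA. The decision procedure per record:

1. Site found in the table and `(ref, alt)` matches its orientation (the
   record's alt may be any listed alternate; multi-allelic sites match on
   any) → `match`, unchanged.
2. Site found and the pair matches with roles exchanged → `flipped`: alleles
   swapped, `β → −β`, `f_alt → 1 − f_alt`. The swap is an involution, and
   harmonizing an already-harmonized record is the identity.
3. Site absent, but one stated allele equals the genome bases at
   `[start, end)` → that allele becomes ref (`genome_resolved`, statistics
   flipped when needed). These records keep their input identifier; only
   table hits receive rsIDs.
4. Otherwise `unresolved`: the record is a categorized reject, never an
   exception.

`|β|`, SE and p-value are never modified — a pure allele swap cannot change
them — only the sign, the alleles and the frequency complement.
Strand-ambiguous palindromic SNVs (A/T, C/G) are resolved by position+allele
match only, with a logged count; no frequency-based disambiguation is
attempted. Effect statistics are normalized to the **alternate allele**
(`effect_allele == alt`), the prevailing eQTL convention.

Targets are annotated from a flat gene model (`target_id → symbol, strand,
TSS`). TSS distance is signed positive when the variant lies downstream of
the TSS in the gene's transcription direction, computed from the 1-based
variant position; unknown targets are annotated `.` with a warning.

Where the input has no FDR column, Benjamini–Hochberg adjustment is applied
per `(target_id, tissue)` group (delegated to
`statsmodels.stats.multitest.multipletests`, verified in the tests against
an independently coded step-up oracle to 1e-12); pre-existing FDR values are
trusted and passed through. Records are then partitioned into SNP and INDEL
tracks (both alleles length 1 ⇒ SNP, else INDEL) with significant subsets
extracted under the *strict* inequality `FDR < threshold` (default 0.05; a
record at exactly the threshold is excluded). Splitting by type before tier
or vice versa is observationally equivalent.

Output layout (16 fixed columns, then passthrough): chrom, start, end,
rsid-or-variant_id, ref, alt, beta, se, pvalue, fdr, alt_allele_freq,
target_id, gene_symbol, target_strand, tss_distance, tissue. Numeric values
are rendered with 6 significant digits, a formatting that round-trips
(format∘parse∘format is stable), which is what makes re-running the standard
steps on harmonized output a byte-level fixed point.

## Chromatin interactions

IDs are assigned 1..N strictly in input order, before sorting, so an
interaction late in the file keeps its high ID wherever it sorts. Each
interaction emits exactly two lines — A (source) and B (target) — keyed on
that anchor's own coordinates and carrying the full interact field set
(name, score, value, experiment, color, both anchors' coordinates/names/
strands), the anchor id as column 19, and any passthrough extras after it.
Because output is anchor-sorted, the two lines of one interaction may be far
apart; pairing is by interaction id, not adjacency. Self-interactions
(identical anchors) are allowed with a warning.

Score/value: a missing value is derived from a positive score as
`−log10(score)` — taken literally, which yields negative values for
score > 1 and null for score 0. Because that relation is dimensionally odd
for a 0–1000 score, an input column explicitly mapped as a p-value-like
significance takes precedence when present: `value = −log10(p)` and a
missing score is derived as `min(1000, round(−10·log10 p))`. With neither
source available both get null sentinels (score 0, value `.`). Both
behaviors are deliberate and this precedence is the package's own choice.
Names follow the colon-joined template
`<data_source>:<id>:score=<score>:value=<value>` with nulls rendered `.`.

## Metadata

Per track: record count, base-pair coverage as the size of the union of
`[start, end)` intervals computed by a single sweep over the sorted rows
(the same rule for all datatypes — QTL and anchor tracks count the distinct
bases their intervals cover), and md5 over the **uncompressed** payload so
identity is independent of compression level. The consolidated project
table has a fixed column order, rows sorted by output path, and contains no
timestamps or hostnames — reruns are byte-identical; run-specific
information goes to the log instead. Two tracks resolving to the same output
path is a hard error naming both.

## Driver and execution modes

`generate_plans` produces one inspectable plan per MDT row (stage list =
standard pre-steps + datatype steps + standard post-steps); `--dry-run`
prints plans without writing. Plans execute in-process in four modes —
sequential, threaded (thread pool across tracks), by-file (process pool
across tracks), by-chromosome (per-track partitioning of the row-wise
stages by normalized chromosome, merged back in original row order before
any whole-file stage). All modes drive the same pure row functions, so
final artifacts are byte-identical by construction; the suite verifies the
digests anyway. FDR grouping runs only after the chromosome merge, because
a target's variants may span partitions; interaction numbering likewise.
Each track writes to a private temporary directory moved into place on
success, a failing track is reported and skipped, and the batch exit status
is non-zero if any track failed.

## Synthetic data

The generator produces a two-chromosome toy genome (10 kb each by default —
small enough that the whole suite runs in about a minute), a site table
whose reference alleles provably equal the genome bases (~5% deletions, ~5%
insertions, ~10% of SNVs multi-allelic), and a gene model with TSSs on both
strands. QTL fixtures render the *same* associations in two dialects (9
columns, tab, 1-based, bare chromosome names vs 19 columns, comma, 0-based,
chr-prefixed, shuffled order, extra passthrough columns). Defaults plant
orientation swaps in 30% of SNV records and draw 1% of variants from
positions absent from the site table but consistent with the genome;
effect sizes are N(0, 0.5²), p-values a uniform/Beta(0.2, 20) mixture with a
20% signal fraction so the 0.05 significance split is non-trivial, and
alt-allele frequencies uniform on (0.01, 0.99). Swaps are planted only for
SNVs (an INDEL swap cannot stay coordinate-consistent, see above).
Interaction fixtures cycle score-only / p-value-only / no-significance rows
and always include one self-interaction and one inter-chromosomal pair;
interval fixtures mix chromosome styles and plant ~5% out-of-range scores
to exercise clamping.

What the generator does **not** emulate: realistic linkage structure,
allele-frequency spectra, genomic clustering of peaks or loops, multi-tissue
studies within one file, or real-resource scale (dbSNP-sized tables,
GENCODE gene counts). Passing tests therefore demonstrate the correctness
of the harmonization logic and the file contracts, not robustness to every
real-world dialect in the wild.

The scalability check times the full QTL pipeline on 10k/40k/160k-row
inputs (best of two runs each) and fits the slope of log-time vs log-size;
sizes chosen as a 16× geometric range that keeps the measurement robust to
timer noise. The slope bound (≤ 1.3) asserts sub-quadratic, near-linear
growth rather than any absolute time.

## Known limitations

- No liftover: the genome build is metadata only.
- No remote inputs; files must be local.
- The variant reference is loaded fully into memory; a tabix-backed
  implementation of the same lookup contract would be the drop-in choice
  for dbSNP-scale tables.
- Standard errors are left untouched by allele harmonization (a pure swap
  cannot change them); no attempt is made to detect mislabeled SE columns.
- The interval-indexing hook for external collection-level search engines
  is limited to emitting the output directory list.
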