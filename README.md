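# fgharmonize

Config-driven harmonization of heterogeneous functional-genomics (FG) data —
annotated genomic intervals (ChIP-seq/ATAC-seq/DNase-seq peaks), QTL summary
statistics (eQTLs, pQTLs, …) and chromatin interactions (Hi-C/3C/4C loop
calls) — into coordinate-sorted, bgzip-compressed, tabix-indexed,
BED-convention tracks with standardized per-track and project-level metadata.

It is written for anyone assembling FG data collections for post-GWAS
annotation and querying: the same assay arrives from different sources with
different delimiters, column names and orders, 0- vs 1-based coordinates,
`chr1` vs `1` chromosome labels, and varying effect-allele conventions.
`fgharmonize` takes one *minimal descriptions table* (MDT, one row of
biological/source/file information per input file) plus a small column-mapping
*file config* per input layout, and emits analysis-ready indexed tracks.

## What it computes

**Standard steps (every datatype).** Column rearrangement into a fixed output
layout, chromosome-name normalization (`1 → chr1`, `MT → chrM`), conversion of
1-based inclusive coordinates to the BED 0-based half-open convention
(`[s, e] → [s−1, e)`), deterministic coordinate sorting, bgzip compression and
tabix indexing. Rows that cannot be harmonized go to a `.rejects` sidecar with
line numbers and reasons; the run continues.

**QTL steps.** Each association is verified against a variant reference table
(the role dbSNP plays in production) with a genome-FASTA fallback, and
re-expressed on the alternate allele: if the record's (ref, alt) pair is
swapped relative to the reference,

```
(ref, alt) → (alt, ref),   β → −β,   f_alt → 1 − f_alt ,
```

with |β| and the p-value always preserved. Resolved records gain rsIDs when
the site is in the table, target-gene annotation (symbol, strand, signed TSS
distance), and — when the input carries no FDR column — Benjamini–Hochberg
adjusted p-values computed per (target, tissue) group:

```
q_(i) = min_{j ≥ i} ( p_(j) · m / j ) ,
```

for a group of m tests. Outputs are split into SNP/INDEL full tracks plus
their significant subsets (FDR < 0.05 by default, strict).

**Chromatin interactions.** Each interaction gets a unique ID in input order;
both anchors are written on separate lines in a UCSC-interact-style layout so
that a region query at *either* anchor retrieves the interaction, with the
anchor id (`17A`/`17B`) tying the pair back together. Score (integer in
[0, 1000]) and value (a double) are filled per the interact conventions when
missing.

**Metadata.** Every output track gets a row with standardized tissue/system
categories from a controlled vocabulary, record count, genomic base-pair
coverage (union of intervals) and the md5 of the uncompressed payload; all
rows consolidate into one deterministic `metadata.tsv` at the project root.

## Worked example

The package ships a synthetic-project generator (also used by the tests), so
a complete runnable example needs no downloads:

```python
from fgharmonize import fixtures
fixtures.gen_project("demo", seed=11, n_qtl=400, n_interactions=90,
                     n_intervals=150)
```

This writes a toy genome + variant reference + gene model, a peak file, the
same 400 eQTL associations in two dialects (9-column TSV and 19-column CSV),
a loop table, the MDT and a `system.ini`. Then:

```console
$ fgh run demo/mdt.tsv --config demo/system.ini --out demo_out --mode threaded
peaks01: ok (1 track(s), 0 reject(s))
eqtl09: ok (4 track(s), 0 reject(s))
eqtl19: ok (4 track(s), 0 reject(s))
loops01: ok (1 track(s), 0 reject(s))
project metadata: demo_out/metadata.tsv
```

Each QTL input yields four tracks (SNP/INDEL × full/significant), placed in a
hierarchy of significance tier / variant type / assay / format / genome build.
The consolidated metadata records the resolved vocabulary categories and file
statistics:

```console
$ cut -f1-2,9-10,14-15 demo_out/metadata.tsv | head -3
output_path	track_id	tissue_category	system_category	n_records	bp_coverage
ChIP-seq/bed6plus/GRCh38/peaks01.bed.gz	peaks01	brain	nervous	150	18193
FDR0.05/INDEL/RNA-seq/bed19/GRCh38/eqtl09.bed.gz	eqtl09	liver	digestive	17	27
```

(`n_records` is the line count of the track; `bp_coverage` the number of
distinct bases its intervals cover.) The outputs are ordinary tabix tracks:

```console
$ tabix demo_out/full/SNP/RNA-seq/bed19/GRCh38/eqtl09.bed.gz chr1:2000-2200 | cut -f1-9 | head -3
chr1	2129	2130	rs10294	C	G	-0.586828	.	0.769556
chr1	2136	2137	rs10296	G	A	0.362612	.	0.920019
chr1	2157	2158	rs10301	A	C	-0.502934	.	0.00209321
```

Columns are chrom, start, end, rsid-or-input-id, ref, alt, β (on the alt
allele), SE, p-value, then FDR, alt-allele frequency, target, gene symbol,
strand, TSS distance, tissue and any passthrough columns. `fgh validate`
checks an MDT and its configs without processing, and `fgh stats <track>`
recomputes a track's statistics.

## Documentation

`docs/methods.md` describes the model and conventions in detail, including
the file-config grammar, the allele-harmonization decision procedure, the
synthetic-data generator's assumptions and the package's known limitations.
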