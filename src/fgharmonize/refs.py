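"""Reference resources for QTL normalization.

``VariantReference`` wraps a variant site table (the role dbSNP plays in
production; any table with the documented columns works) plus random access
to the genome FASTA, which serves as the fallback for sites absent from the
table.  ``GeneModel`` is a flat target lookup giving symbol, strand and TSS
position (GENCODE-derived in production).

Variant table columns (TSV, optionally bgzipped):
``chrom  start(0-based)  end  rsid  ref  alts(comma-separated)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pysam


@dataclass(frozen=True)
class VariantSite:
    rsid: str
    ref: str
    alts: tuple


class VariantReference:
    """Variant site lookup keyed on (chrom, start, end) + genome base access."""

    def __init__(self, table_path, fasta_path):
        self.table_path = Path(table_path)
        self.fasta_path = Path(fasta_path)
        self._sites: dict[tuple, VariantSite] = {}
        self._load_table()
        self._fasta = None  # opened lazily; pysam handles are not picklable

    def _load_table(self):
        opener = gzip.open if self.table_path.suffix == ".gz" else open
        with opener(self.table_path, "rt") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chrom, start, end, rsid, ref, alts = line.split("\t")[:6]
                key = (chrom, int(start), int(end))
                self._sites[key] = VariantSite(
                    rsid=rsid, ref=ref.upper(),
                    alts=tuple(a.upper() for a in alts.split(",") if a),
                )

    def lookup(self, chrom: str, start: int, end: int) -> VariantSite | None:
        return self._sites.get((chrom, start, end))

    def genome_bases(self, chrom: str, start: int, end: int) -> str:
        """Genome sequence at [start, end), upper-cased; "" if out of range."""
        if self._fasta is None:
            self._fasta = pysam.FastaFile(str(self.fasta_path))
        if chrom not in self._fasta.references:
            return ""
        return self._fasta.fetch(chrom, start, end).upper()

    def __len__(self):
        return len(self._sites)


class GeneModel:
    """target_id -> (gene_symbol, strand, tss_position) lookup.

    Table columns (TSV with header):
    ``target_id  gene_symbol  chrom  strand  tss_position`` (1-based TSS).
    """

    def __init__(self, path):
        self.path = Path(path)
        self._genes: dict[str, tuple] = {}
        with open(self.path) as handle:
            header = handle.readline()
            assert header.startswith("target_id"), "gene model missing header"
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    continue
                target_id, symbol, chrom, strand, tss = parts[:5]
                self._genes[target_id] = (symbol, strand, chrom, int(tss))

    def lookup(self, target_id: str):
        """Return (gene_symbol, strand, chrom, tss_position) or None."""
        return self._genes.get(target_id)

    def __len__(self):
        return len(self._genes)
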