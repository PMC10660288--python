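"""Synthetic input generation with recorded ground truth.

Everything the pipelines read can be generated here: a toy two-chromosome
genome with a consistent variant site table and gene model, QTL
summary-statistics files rendered in two dialects (a compact 9-column table
and a wide 19-column table, mirroring how the same associations circulate
in different column layouts), interaction tables with mixed significance
columns, shuffled BED-like interval files, plus the MDT, file configs and
system INI that tie a project together.

Each generator records a manifest of ground truth (true alt-oriented
effect sizes, planted allele-orientation swaps, reference membership,
interaction anchor pairs, interval sets) so recovery tests can compare the
harmonized output against what was actually planted.  The same seed always
reproduces byte-identical fixtures.

Planted orientation swaps are restricted to single-nucleotide variants:
swapping ref/alt for an INDEL would change the record's [start, end)
footprint (end = start + len(ref)) and could not stay coordinate-consistent
with the genome.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .qtl import fmt

BASES = "ACGT"


@dataclass
class FixtureManifest:
    seed: int
    kind: str
    ground_truth: list = field(default_factory=list)
    dialects: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "FixtureManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reference resources


def gen_reference(outdir, seed: int, chrom_lengths=(10000, 10000),
                  n_sites_per_chrom: int = 1500, n_genes: int = 60) -> dict:
    """Toy genome FASTA + consistent variant site table + gene model.

    Every site's ref allele equals the genome bases at its coordinates;
    ~10% of sites are INDELs (1-2 bp insertions/deletions), the rest SNVs,
    some multi-allelic.  Genes carry TSSs on both strands.

    Returns a dict with paths ``genome``, ``variants``, ``genes`` and the
    in-memory site list (used by :func:`gen_qtl_dataset`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": int(n) for i, n in enumerate(chrom_lengths)}
    seqs = {c: "".join(rng.choice(list(BASES), size=n)) for c, n in chroms.items()}

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as handle:
        for chrom, seq in seqs.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i:i + 60] + "\n")
    fai = Path(str(genome_path) + ".fai")
    if fai.exists():
        os.remove(fai)
    pysam.faidx(str(genome_path))

    sites = []  # (chrom, start, end, rsid, ref, alts)
    rs_counter = 10000
    for chrom, length in chroms.items():
        # leave a 2 bp safety margin so deletion refs stay in range
        positions = np.sort(rng.choice(
            np.arange(1, length - 2), size=min(n_sites_per_chrom, length // 4),
            replace=False,
        ))
        for pos in positions:
            start = int(pos)
            ref_base = seqs[chrom][start]
            roll = rng.random()
            if roll < 0.05:  # deletion: ref spans 2 genome bases
                ref = seqs[chrom][start:start + 2]
                alts = (ref_base,)
                end = start + 2
            elif roll < 0.10:  # insertion
                ref = ref_base
                alts = (ref_base + rng.choice(list(BASES)),)
                end = start + 1
            else:
                ref = ref_base
                others = [b for b in BASES if b != ref_base]
                k = 2 if rng.random() < 0.1 else 1
                alts = tuple(rng.choice(others, size=k, replace=False))
                end = start + 1
            sites.append((chrom, start, end, f"rs{rs_counter}", ref, alts))
            rs_counter += 1

    plain = outdir / "variants.tsv"
    with open(plain, "w") as handle:
        for chrom, start, end, rsid, ref, alts in sites:
            handle.write(f"{chrom}\t{start}\t{end}\t{rsid}\t{ref}\t{','.join(alts)}\n")
    variants_path = outdir / "variants.tsv.gz"
    pysam.tabix_compress(str(plain), str(variants_path), force=True)
    os.remove(plain)
    pysam.tabix_index(str(variants_path), seq_col=0, start_col=1, end_col=2,
                      zerobased=True, force=True)

    genes_path = outdir / "genes.tsv"
    chrom_names = list(chroms)
    with open(genes_path, "w") as handle:
        handle.write("target_id\tgene_symbol\tchrom\tstrand\ttss_position\n")
        for i in range(n_genes):
            chrom = chrom_names[i % len(chrom_names)]
            tss = int(rng.integers(100, chroms[chrom] - 100))
            strand = "+" if i % 2 == 0 else "-"
            handle.write(f"GENE{i:04d}\tSYM{i:04d}\t{chrom}\t{strand}\t{tss}\n")

    return {"genome": genome_path, "variants": variants_path,
            "genes": genes_path, "sites": sites, "chrom_lengths": chroms}


# ---------------------------------------------------------------------------
# QTL datasets


_QTL9_COLUMNS = ("gene_id", "variant_id", "chromosome", "position",
                 "ref", "alt", "maf", "beta", "pvalue")

_QTL19_EXTRAS = ("molecular_trait_object_id", "ma_samples", "ma_count", "anc_af",
                 "type", "ac", "an", "median_tpm", "r2", "study_label")


def gen_qtl_dataset(outdir, reference: dict, n_variants: int, n_genes: int,
                    flip_fraction: float, missing_ref_fraction: float,
                    seed: int, unknown_target_fraction: float = 0.02,
                    signal_fraction: float = 0.2) -> dict:
    """The same associations rendered in two dialects, with ground truth.

    Dialect A: 9 columns, tab-delimited, header, 1-based position, bare
    chromosome names.  Dialect B: 19 columns, comma-delimited, header,
    0-based start/end, chr-prefixed names, shuffled column order, 10 extra
    columns (three of them configured as passthrough).

    ``flip_fraction`` of SNV records are rendered in swapped-allele
    orientation (alleles exchanged, beta negated, alt frequency
    complemented); ``missing_ref_fraction`` of records use variants absent
    from the site table but consistent with the genome, exercising the
    FASTA fallback.  The manifest records, per record: true alt-oriented
    beta, planted orientation, reference membership and expected rsID.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sites = reference["sites"]
    chrom_lengths = reference["chrom_lengths"]
    occupied = {(c, s) for c, s, *_ in sites}
    genome = pysam.FastaFile(str(reference["genome"]))

    with open(reference["genes"]) as handle:
        gene_ids = [line.split("\t")[0] for line in handle.readlines()[1:]]
    gene_pool = gene_ids[:n_genes] if n_genes <= len(gene_ids) else gene_ids

    n_missing = int(round(n_variants * missing_ref_fraction))
    truth, rows = [], []
    # novel SNVs absent from the site table, consistent with the genome
    novel = []
    chrom_names = list(chrom_lengths)
    while len(novel) < n_missing:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(1, chrom_lengths[chrom] - 2))
        if (chrom, start) in occupied:
            continue
        occupied.add((chrom, start))
        ref = genome.fetch(chrom, start, start + 1).upper()
        alt = str(rng.choice([b for b in BASES if b != ref]))
        novel.append((chrom, start, start + 1, None, ref, (alt,)))

    site_idx = rng.integers(0, len(sites), size=n_variants - n_missing)
    chosen = [sites[i] for i in site_idx] + novel
    order = rng.permutation(len(chosen))

    for rank, i in enumerate(order):
        chrom, start, end, rsid, ref, alts = chosen[i]
        alt = str(alts[int(rng.integers(len(alts)))])
        is_snv = len(ref) == 1 and len(alt) == 1
        gene = gene_pool[int(rng.integers(len(gene_pool)))]
        if rng.random() < unknown_target_fraction:
            gene = f"NOVELTARGET{rank:05d}"
        beta = float(fmt(rng.normal(0.0, 0.5)))
        if rng.random() < signal_fraction:
            pvalue = float(fmt(max(1e-30, rng.beta(0.2, 20.0) * 0.05)))
        else:
            pvalue = float(fmt(rng.uniform(1e-6, 1.0)))
        af = float(fmt(rng.uniform(0.01, 0.99)))
        flipped = bool(is_snv and rng.random() < flip_fraction)
        if flipped:
            out_ref, out_alt = alt, ref
            out_beta, out_af = float(fmt(-beta)), float(fmt(1.0 - af))
        else:
            out_ref, out_alt = ref, alt
            out_beta, out_af = beta, af
        pos1 = start + 1
        variant_id = f"{chrom}_{pos1}_{out_ref}_{out_alt}"
        rows.append({
            "chrom": chrom, "pos1": pos1, "start0": start, "end0": end,
            "ref": out_ref, "alt": out_alt, "beta": out_beta, "af": out_af,
            "pvalue": pvalue, "gene": gene, "variant_id": variant_id,
        })
        truth.append({
            "variant_id": variant_id,
            "key": [chrom, start, end],
            "true_beta": beta, "true_af": af, "pvalue": pvalue,
            "flipped": flipped, "in_reference": rsid is not None,
            "rsid": rsid, "target_id": gene,
            "variant_type": "SNP" if is_snv else "INDEL",
        })

    # dialect A: 9 columns, tab, header, 1-based, bare chromosomes
    path_a = outdir / "qtl_9col.tsv"
    with open(path_a, "w") as handle:
        handle.write("\t".join(_QTL9_COLUMNS) + "\n")
        for r in rows:
            handle.write("\t".join([
                r["gene"], r["variant_id"], r["chrom"][3:], str(r["pos1"]),
                r["ref"], r["alt"], fmt(r["af"]), fmt(r["beta"]), fmt(r["pvalue"]),
            ]) + "\n")
    (outdir / "qtl_9col.config").write_text(
        "delimiter = tab\nhas_header = true\ncoordinate_base = 1\n"
        "chrom_style = bare\n"
        "chromosome -> chrom\nposition -> pos\nref -> ref\nalt -> alt\n"
        "maf -> alt_allele_freq\nbeta -> beta\npvalue -> pvalue\n"
        "variant_id -> variant_id\ngene_id -> target_id\n"
    )

    # dialect B: 19 columns, comma, header, 0-based start/end, chr-prefixed
    cols_b = ["study_label", "gene_id", "chrom", "interval_start", "interval_end",
              "reference_allele", "alternate_allele", "effect", "p_value",
              "alt_freq", "snp"] + [c for c in _QTL19_EXTRAS
                                    if c != "study_label"][:8]
    path_b = outdir / "qtl_19col.csv"
    with open(path_b, "w") as handle:
        handle.write(",".join(cols_b) + "\n")
        for r in rows:
            extras = ["traitobj", "101", "12", "0.31", "SNP_panel", "24",
                      "202", "5.5"]
            handle.write(",".join([
                "studyX", r["gene"], r["chrom"], str(r["start0"]),
                str(r["end0"]), r["ref"], r["alt"], fmt(r["beta"]),
                fmt(r["pvalue"]), fmt(r["af"]), r["variant_id"],
            ] + extras) + "\n")
    (outdir / "qtl_19col.config").write_text(
        "delimiter = comma\nhas_header = true\ncoordinate_base = 0\n"
        "chrom_style = chr_prefixed\n"
        "chrom -> chrom\ninterval_start -> start\ninterval_end -> end\n"
        "reference_allele -> ref\nalternate_allele -> alt\n"
        "effect -> beta\np_value -> pvalue\nalt_freq -> alt_allele_freq\n"
        "snp -> variant_id\ngene_id -> target_id\n"
        "passthrough = study_label, molecular_trait_object_id, median_tpm\n"
    )

    manifest = FixtureManifest(
        seed=seed, kind="qtl", ground_truth=truth,
        dialects={"9col": path_a.name, "19col": path_b.name},
        params={"n_variants": n_variants, "n_genes": n_genes,
                "flip_fraction": flip_fraction,
                "missing_ref_fraction": missing_ref_fraction},
    )
    manifest.save(outdir / "qtl_manifest.json")
    return {"9col": path_a, "19col": path_b,
            "9col_config": outdir / "qtl_9col.config",
            "19col_config": outdir / "qtl_19col.config",
            "manifest": manifest}


# ---------------------------------------------------------------------------
# interactions


def gen_interactions(outdir, n: int, seed: int,
                     chrom_lengths=None) -> dict:
    """Anchor-pair table with mixed significance columns and passthrough.

    Rows cycle through three significance renderings (score only, p-value
    only, neither); the file includes at least one self-interaction and at
    least one inter-chromosomal pair.  Coordinates are 1-based inclusive
    with bare chromosome names, exercising both standard conversions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 10000, "chr2": 10000}
    chroms = list(chrom_lengths)

    def anchor(chrom):
        length = chrom_lengths[chrom]
        width = int(rng.integers(200, 800))
        start1 = int(rng.integers(1, length - width))
        return start1, start1 + width - 1  # 1-based inclusive

    rows, truth = [], []
    for i in range(n):
        c1 = chroms[int(rng.integers(len(chroms)))]
        if i == 1 and n > 1:  # guaranteed inter-chromosomal pair
            c2 = chroms[(chroms.index(c1) + 1) % len(chroms)]
        else:
            c2 = chroms[int(rng.integers(len(chroms)))]
        s1, e1 = anchor(c1)
        if i == 0:  # guaranteed self-interaction
            c2, (s2, e2) = c1, (s1, e1)
        else:
            s2, e2 = anchor(c2)
        kind = i % 3
        score = str(int(rng.integers(1, 1001))) if kind == 0 else "."
        pval = fmt(rng.uniform(1e-8, 0.5)) if kind == 1 else "."
        rows.append([c1[3:], str(s1), str(e1), c2[3:], str(s2), str(e2),
                     score, pval, f"cellline{i % 4}", str(i % 2 + 1)])
        truth.append({"id": i + 1,
                      "source": [c1, s1 - 1, e1], "target": [c2, s2 - 1, e2],
                      "score": None if score == "." else int(score),
                      "pvalue": None if pval == "." else float(pval)})

    path = outdir / "loops.tsv"
    with open(path, "w") as handle:
        handle.write("chr_a\tstart_a\tend_a\tchr_b\tstart_b\tend_b\t"
                     "score\tpval\tcell_line\treplicate\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    (outdir / "loops.config").write_text(
        "delimiter = tab\nhas_header = true\ncoordinate_base = 1\n"
        "chr_a -> chrom1\nstart_a -> start1\nend_a -> end1\n"
        "chr_b -> chrom2\nstart_b -> start2\nend_b -> end2\n"
        "score -> score\npval -> pvalue\n"
        "passthrough = cell_line, replicate\n"
    )
    manifest = FixtureManifest(seed=seed, kind="interactions",
                               ground_truth=truth, params={"n": n})
    manifest.save(outdir / "interactions_manifest.json")
    return {"file": path, "config": outdir / "loops.config", "manifest": manifest}


# ---------------------------------------------------------------------------
# intervals


def gen_intervals(outdir, n: int, seed: int, chrom_lengths=None,
                  out_of_range_fraction: float = 0.05) -> dict:
    """Shuffled BED-like intervals with mixed chromosome styles.

    ``out_of_range_fraction`` of scores fall outside [0, 1000] to exercise
    clamping; the manifest records the sorted true interval set and the
    expected clamp count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 10000, "chr2": 10000}
    chroms = list(chrom_lengths)

    rows, truth, n_clamped = [], [], 0
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(50, 500))
        start = int(rng.integers(0, chrom_lengths[chrom] - width))
        end = start + width
        clamped = rng.random() < out_of_range_fraction
        if clamped:
            score = int(rng.choice([-50, 1500, 2400]))
            n_clamped += 1
        else:
            score = int(rng.integers(0, 1001))
        strand = str(rng.choice(["+", "-", "."]))
        style = chrom if rng.random() < 0.5 else chrom[3:]  # mixed naming
        rows.append([style, str(start), str(end), f"peak_{i + 1}",
                     str(score), strand])
        truth.append([chrom, start, end, f"peak_{i + 1}",
                      min(1000, max(0, score)), strand, clamped])
    perm = rng.permutation(n)
    rows = [rows[i] for i in perm]

    path = outdir / "peaks.tsv"
    with open(path, "w") as handle:
        handle.write("seqname\tpeak_start\tpeak_end\tpeak_name\tsignal\tstrand\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")
    (outdir / "peaks.config").write_text(
        "delimiter = tab\nhas_header = true\ncoordinate_base = 0\n"
        "chrom_style = auto\n"
        "seqname -> chrom\npeak_start -> start\npeak_end -> end\n"
        "peak_name -> name\nsignal -> score\nstrand -> strand\n"
    )
    manifest = FixtureManifest(
        seed=seed, kind="intervals", ground_truth=truth,
        params={"n": n, "n_clamped": n_clamped},
    )
    manifest.save(outdir / "intervals_manifest.json")
    return {"file": path, "config": outdir / "peaks.config", "manifest": manifest}


# ---------------------------------------------------------------------------
# whole project


def gen_project(outdir, seed: int, n_qtl: int = 400, n_interactions: int = 90,
                n_intervals: int = 150, flip_fraction: float = 0.3,
                missing_ref_fraction: float = 0.01) -> dict:
    """A complete runnable project: reference, data files, MDT, system INI.

    The MDT describes four tracks: one interval track, the same QTL dataset
    in both dialects, and one interaction track.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = gen_reference(outdir / "reference", seed=seed)
    qtl_fx = gen_qtl_dataset(outdir, reference, n_variants=n_qtl, n_genes=40,
                             flip_fraction=flip_fraction,
                             missing_ref_fraction=missing_ref_fraction,
                             seed=seed + 1)
    ia_fx = gen_interactions(outdir, n=n_interactions, seed=seed + 2,
                             chrom_lengths=reference["chrom_lengths"])
    iv_fx = gen_intervals(outdir, n=n_intervals, seed=seed + 3,
                          chrom_lengths=reference["chrom_lengths"])

    mdt_path = outdir / "mdt.tsv"
    header = ["track_id", "datatype", "biosample_term", "biosample_type",
              "life_stage", "assay_type", "genome_build", "data_source",
              "doi", "file_path", "config_path", "antibody"]
    mdt_rows = [
        ["peaks01", "intervals", "hippocampus", "tissue", "adult", "ChIP-seq",
         "GRCh38/hg38", "TOYPROJ", "10.0000/toy", "peaks.tsv", "peaks.config",
         "H3K27ac"],
        ["eqtl09", "qtl", "liver", "tissue", "adult", "RNA-seq",
         "GRCh38/hg38", "TOYPROJ", "10.0000/toy", "qtl_9col.tsv",
         "qtl_9col.config", ""],
        ["eqtl19", "qtl", "liver", "tissue", "adult", "RNA-seq",
         "GRCh38/hg38", "TOYPROJ", "10.0000/toy", "qtl_19col.csv",
         "qtl_19col.config", ""],
        ["loops01", "interactions", "left ventricle", "tissue", "adult",
         "Hi-C", "GRCh38/hg38", "TOY3D", "10.0000/toy", "loops.tsv",
         "loops.config", ""],
    ]
    with open(mdt_path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in mdt_rows:
            handle.write("\t".join(row) + "\n")

    ini_path = outdir / "system.ini"
    ini_path.write_text(
        "[references]\n"
        "variant_reference = reference/variants.tsv.gz\n"
        "genome_fasta = reference/genome.fa\n"
        "gene_model = reference/genes.tsv\n"
        "\n[defaults]\nfdr_threshold = 0.05\n"
    )
    return {"mdt": mdt_path, "ini": ini_path, "reference": reference,
            "qtl": qtl_fx, "interactions": ia_fx, "intervals": iv_fx}
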