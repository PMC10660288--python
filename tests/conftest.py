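"""Shared fixtures: a tiny hand-crafted variant reference for allele-level
unit tests, and a session-scoped synthetic project executed once."""

import gzip
import hashlib
from pathlib import Path

import pysam
import pytest

from fgharmonize import driver, fixtures
from fgharmonize.refs import GeneModel, VariantReference

# 20 bp toy chromosome; position i holds MINI_SEQ[i] (0-based)
MINI_SEQ = "ACGTACGTACGTACGTACGT"

# chrom start end rsid ref alts — every ref equals the genome bases
MINI_SITES = [
    ("chr1", 5, 6, "rs555", "C", "G"),        # match site
    ("chr1", 7, 8, "rs777", "T", "C"),        # swap site (rec C/T is flipped)
    ("chr1", 11, 12, "rs111", "T", "A,G"),    # multi-allelic
    ("chr1", 13, 14, "rs131", "A", "AT"),     # insertion site
]


@pytest.fixture(scope="session")
def mini_ref(tmp_path_factory) -> VariantReference:
    root = tmp_path_factory.mktemp("mini_ref")
    fasta = root / "genome.fa"
    fasta.write_text(f">chr1\n{MINI_SEQ}\n")
    pysam.faidx(str(fasta))
    table = root / "variants.tsv"
    with open(table, "w") as handle:
        for chrom, start, end, rsid, ref, alts in MINI_SITES:
            handle.write(f"{chrom}\t{start}\t{end}\t{rsid}\t{ref}\t{alts}\n")
    return VariantReference(table, fasta)


@pytest.fixture(scope="session")
def mini_genes(tmp_path_factory) -> GeneModel:
    root = tmp_path_factory.mktemp("mini_genes")
    path = root / "genes.tsv"
    path.write_text(
        "target_id\tgene_symbol\tchrom\tstrand\ttss_position\n"
        "GENEPLUS\tSYMP\tchr1\t+\t1000\n"
        "GENEMINUS\tSYMM\tchr1\t-\t2000\n"
    )
    return GeneModel(path)


@pytest.fixture(scope="session")
def project(tmp_path_factory):
    """A generated project (reference + data + MDT + INI), not yet executed."""
    root = tmp_path_factory.mktemp("project")
    paths = fixtures.gen_project(root / "proj", seed=7)
    system = driver.SystemConfig.from_ini(paths["ini"])
    return {"paths": paths, "system": system, "root": root}


@pytest.fixture(scope="session")
def harmonized(project):
    """The session project executed once in sequential mode."""
    out = project["root"] / "out_sequential"
    plans = driver.generate_plans(project["paths"]["mdt"], project["system"])
    report = driver.execute(plans, out, project["system"], mode="sequential")
    assert report.ok, report.summary()
    return {"out": out, "report": report, "plans": plans, **project}


def track_digests(out_dir) -> dict:
    """md5 of the uncompressed payload of every track under a directory."""
    digests = {}
    for path in sorted(Path(out_dir).rglob("*.bed.gz")):
        with gzip.open(path, "rb") as handle:
            digests[str(path.relative_to(out_dir))] = hashlib.md5(
                handle.read()).hexdigest()
    return digests


def read_track_rows(path):
    with gzip.open(path, "rt") as handle:
        return [line.rstrip("\n").split("\t") for line in handle]
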