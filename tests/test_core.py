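"""Type-independent steps: chromosome/coordinate normalization, column
mapping, sorting + indexing, and the output hierarchy."""

import pytest

from fgharmonize.config import FileConfig
from fgharmonize.core import (build_output_path, clamp_score,
                              convert_coordinates, normalize_chrom,
                              process_interval_records, query_track,
                              read_mapped_rows, sort_compress_index)
from fgharmonize.errors import RowRejected


@pytest.mark.parametrize("raw, expected", [
    ("1", "chr1"), ("22", "chr22"), ("chr1", "chr1"), ("CHR4", "chr4"),
    ("MT", "chrM"), ("chrMT", "chrM"), ("M", "chrM"),
    ("X", "chrX"), ("x", "chrX"), ("chrY", "chrY"),
    ("GL000195.1", "chrGL000195.1"), (" 7 ", "chr7"),
])
def test_normalize_chrom(raw, expected):
    assert normalize_chrom(raw) == expected
    # idempotence: a normalized name is a fixed point
    assert normalize_chrom(expected) == expected


@pytest.mark.parametrize("bad", ["", "   ", "chr"])
def test_normalize_chrom_rejects_empty(bad):
    with pytest.raises(RowRejected):
        normalize_chrom(bad)


@pytest.mark.parametrize("start, end, base, expected", [
    (100, 200, 1, (99, 200)),   # 1-based inclusive -> 0-based half-open
    (99, 200, 0, (99, 200)),    # 0-based passes through
    (100, None, 1, (99, 100)),  # single position (SNP)
    (5, None, 0, (5, 6)),
    (1, 1, 1, (0, 1)),
])
def test_convert_coordinates(start, end, base, expected):
    assert convert_coordinates(start, end, base) == expected


@pytest.mark.parametrize("start, end, base", [
    (0, 10, 1),    # below the coordinate base
    (100, 50, 1),  # end before start
    ("x", 10, 0),  # non-numeric
])
def test_convert_coordinates_rejects(start, end, base):
    with pytest.raises(RowRejected):
        convert_coordinates(start, end, base)


def write_table(tmp_path, text, name="t.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_map_columns_reorders_to_standard_layout(tmp_path):
    # input order (score-like, chrom, start, end); mapped to standard order
    path = write_table(tmp_path, "55\t1\t100\t200\n")
    cfg = FileConfig(column_map={"chrom": 2, "start": 3, "end": 4, "score": 1},
                     has_header=False)
    rows, rejects = process_interval_records(
        read_mapped_rows(path, cfg, "intervals"), cfg)
    assert rejects == []
    assert rows == [["chr1", "99", "200", ".", "55", "."]]


def test_map_columns_short_row_rejected_with_line_number(tmp_path):
    path = write_table(tmp_path, "chr1\t100\t200\nchr1\t300\n")
    cfg = FileConfig(column_map={"chrom": 1, "start": 2, "end": 3},
                     has_header=False, coordinate_base=0)
    rows, rejects = process_interval_records(
        read_mapped_rows(path, cfg, "intervals"), cfg)
    assert len(rows) == 1
    assert len(rejects) == 1
    assert rejects[0][0] == 2  # line number
    assert "short-row" in rejects[0][1]


def test_header_name_resolution(tmp_path):
    path = write_table(tmp_path, "pv\tc\ts\te\n0.5\t2\t10\t20\n")
    cfg = FileConfig(column_map={"chrom": "c", "start": "s", "end": "e"},
                     coordinate_base=0)
    rows, rejects = process_interval_records(
        read_mapped_rows(path, cfg, "intervals"), cfg)
    assert rows == [["chr2", "10", "20", ".", ".", "."]]


def test_conservation_accepted_plus_rejects_equals_input(tmp_path):
    lines = ["chr1\t%d\t%d" % (i, i + 10) for i in range(20)]
    lines[3] = "chr1\t50"          # short
    lines[11] = "chr1\t99\t40"     # end < start
    path = write_table(tmp_path, "\n".join(lines) + "\n")
    cfg = FileConfig(column_map={"chrom": 1, "start": 2, "end": 3},
                     has_header=False, coordinate_base=0)
    rows, rejects = process_interval_records(
        read_mapped_rows(path, cfg, "intervals"), cfg)
    assert len(rows) + len(rejects) == 20
    assert len(rejects) == 2


class TestSortCompressIndex:
    def test_sorted_output_and_duplicates_adjacent(self, tmp_path):
        records = [
            ["chr2", "5", "10", "c"],
            ["chr1", "300", "400", "b"],
            ["chr1", "100", "200", "a"],
            ["chr1", "100", "200", "a"],  # duplicate retained
        ]
        track = sort_compress_index(records, tmp_path / "t.bed.gz")
        assert track.n_records == 4
        from conftest import read_track_rows
        rows = read_track_rows(track.data_path)
        assert [r[3] for r in rows] == ["a", "a", "b", "c"]
        assert track.index_path.exists()

    def test_region_query_matches_linear_scan(self, tmp_path):
        records = [["chr1", "100", "200", "x"], ["chr1", "300", "400", "y"]]
        track = sort_compress_index(records, tmp_path / "t.bed.gz")
        hits = query_track(track, "chr1", 150, 160)
        oracle = [r for r in records
                  if r[0] == "chr1" and int(r[1]) < 160 and int(r[2]) > 150]
        assert hits == oracle
        assert [r[3] for r in hits] == ["x"]

    def test_empty_track_is_valid(self, tmp_path):
        track = sort_compress_index([], tmp_path / "empty.bed.gz")
        assert track.n_records == 0
        assert track.data_path.exists()
        assert query_track(track, "chr1", 0, 1000) == []


class TestOutputPath:
    def test_significant_snp_qtl_layout(self):
        path = build_output_path("trk9", "qtl", "RNA-seq", "GRCh38/hg38",
                                 significance_tier="FDR0.05", variant_type="SNP",
                                 format_type="bed19")
        assert str(path) == "FDR0.05/SNP/RNA-seq/bed19/GRCh38/trk9.bed.gz"

    def test_intervals_omit_inapplicable_tiers(self):
        path = build_output_path("marks", "intervals", "ChIP-seq", "GRCh37/hg19")
        assert str(path) == "ChIP-seq/bed6plus/GRCh37/marks.bed.gz"

    def test_interactions_layout(self):
        path = build_output_path("hic1", "interactions", "Hi-C", "GRCh38/hg38")
        assert str(path) == "Hi-C/bedInteract/GRCh38/hic1.bed.gz"


@pytest.mark.parametrize("raw, expected", [
    ("500", "500"), ("1500", "1000"), ("-3", "0"), (".", "."), ("", "."),
])
def test_clamp_score(raw, expected):
    assert clamp_score(raw) == expected
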