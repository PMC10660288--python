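"""Plan generation, execution modes, failure isolation and the CLI surface."""

import pytest
from click.testing import CliRunner

from conftest import track_digests
from fgharmonize import cli, driver
from fgharmonize.errors import ValidationError


class TestGeneratePlans:
    def test_one_plan_per_row_with_type_specific_stages(self, project):
        plans = driver.generate_plans(project["paths"]["mdt"], project["system"])
        by_type = {p.datatype: p for p in plans}
        assert len(plans) == 4
        assert "harmonize_alleles" in by_type["qtl"].stages
        assert "expand_anchors" in by_type["interactions"].stages
        assert "harmonize_alleles" not in by_type["intervals"].stages
        for p in plans:
            assert p.stages[:4] == ["read_input", "map_columns",
                                    "normalize_chrom", "convert_coordinates"]
            assert p.stages[-5:] == ["sort", "bgzip_compress", "tabix_index",
                                     "track_stats", "metadata"]

    def test_qtl_plan_emits_four_output_paths(self, project):
        plans = driver.generate_plans(project["paths"]["mdt"], project["system"])
        qtl = next(p for p in plans if p.datatype == "qtl")
        assert len(qtl.output_paths) == 4

    def test_fail_fast_on_any_bad_config(self, project):
        proj_dir = project["paths"]["mdt"].parent
        lines = project["paths"]["mdt"].read_text().splitlines()
        # point one row at a config with a bogus field mapping
        (proj_dir / "broken.config").write_text(
            "1 -> chrom\n2 -> start\n3 -> end\n4 -> nonsense\n")
        lines[1] = lines[1].replace("peaks.config", "broken.config")
        bad = proj_dir / "mdt_bad.tsv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="nonsense"):
            driver.generate_plans(bad, project["system"])

    def test_qtl_requires_references(self, project):
        with pytest.raises(ValidationError, match="variant_reference"):
            driver.generate_plans(project["paths"]["mdt"], driver.SystemConfig())

    def test_plans_are_inspectable(self, project):
        plans = driver.generate_plans(project["paths"]["mdt"], project["system"])
        text = plans[0].describe()
        assert "stage:" in text and "output:" in text


class TestExecute:
    @pytest.mark.parametrize("mode", ["threaded", "by_chromosome", "by_file"])
    def test_modes_match_sequential_digests(self, harmonized, mode):
        out = harmonized["root"] / f"out_{mode}"
        report = driver.execute(harmonized["plans"], out, harmonized["system"],
                                mode=mode)
        assert report.ok
        assert track_digests(out) == track_digests(harmonized["out"])

    def test_failing_track_is_isolated(self, project, tmp_path):
        plans = driver.generate_plans(project["paths"]["mdt"], project["system"])
        plans[0].input_path = tmp_path / "vanished.tsv"  # unreadable input
        report = driver.execute(plans, tmp_path / "out", project["system"])
        statuses = {r.track_id: r.status for r in report.results}
        assert statuses[plans[0].track_id] == "failed"
        assert sum(1 for s in statuses.values() if s == "ok") == 3
        assert not report.ok

    def test_rerun_metadata_byte_identical(self, harmonized):
        out2 = harmonized["root"] / "out_rerun"
        report = driver.execute(harmonized["plans"], out2, harmonized["system"])
        assert report.metadata_path.read_text() == \
            harmonized["report"].metadata_path.read_text()

    def test_output_directories_hook(self, harmonized):
        dirs = driver.output_directories(harmonized["out"])
        # 4 significance/variant-type QTL leaves (shared by both dialect
        # tracks) + intervals + interactions
        assert len(dirs) == 6
        assert all(any(p.suffix == ".gz" for p in d.iterdir()) for d in dirs)

    def test_unknown_mode_rejected(self, harmonized):
        with pytest.raises(ValidationError, match="mode"):
            driver.execute([], harmonized["root"] / "x", mode="cluster")


class TestCli:
    def test_validate_ok(self, project):
        runner = CliRunner()
        result = runner.invoke(cli.main, [
            "validate", str(project["paths"]["mdt"]),
            "--config", str(project["paths"]["ini"]),
        ])
        assert result.exit_code == 0, result.output
        assert "4 track(s)" in result.output

    def test_dry_run_writes_nothing(self, project, tmp_path):
        runner = CliRunner()
        out = tmp_path / "never"
        result = runner.invoke(cli.main, [
            "run", str(project["paths"]["mdt"]),
            "--config", str(project["paths"]["ini"]),
            "--out", str(out), "--dry-run",
        ])
        assert result.exit_code == 0, result.output
        assert "stage:" in result.output
        assert not out.exists()

    def test_stats_command(self, harmonized):
        track = next(harmonized["out"].rglob("peaks01.bed.gz"))
        runner = CliRunner()
        result = runner.invoke(cli.main, ["stats", str(track)])
        assert result.exit_code == 0
        assert "n_records\t150" in result.output
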