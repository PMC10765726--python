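"""Recipe evaluation: sidecar contract, checksums, verification, determinism."""

import subprocess

import pytest
import yaml

from recipekit import (
    CollisionError,
    DataRecord,
    EvaluationError,
    OutputCollectionError,
    OutputSpec,
    ParameterSpec,
    RunnerSpec,
    collect_outputs,
    compute_md5,
    evaluate,
    make_recipe,
    register_runner,
    verify,
    write_md5_manifest,
)
from recipekit.evaluator import sidecar_prefix
from recipekit.recipe import resolve_bindings


class TestEvaluate:
    def test_sidecar_contract(self, hello_result):
        outdir = hello_result.outdir
        assert (outdir / "hello.txt").read_text() == "Hello World\n"
        prefix = hello_result.prefix
        assert prefix == "echo_out_Hello-World_hello"
        for ext in (".yml", ".sh", ".cwl", ".md5"):
            assert (outdir / f"{prefix}{ext}").exists(), ext
        meta = hello_result.meta
        assert meta.parameters == {"input": "Hello World", "outfile": "hello"}
        assert meta.notes == ["greeting", "demo data"]

    def test_yml_sidecar_fields(self, hello_result):
        doc = yaml.safe_load(hello_result.sidecars["yml"].read_text())
        assert doc["recipe"] == "echo_out"
        assert doc["version"] == "1.0.0"
        assert doc["origin"] == "local"
        # ISO-8601 UTC with seconds precision
        from datetime import datetime

        datetime.strptime(doc["date"], "%Y-%m-%dT%H:%M:%SZ")
        (entry,) = doc["outputs"]
        assert entry["path"] == "hello.txt"
        assert entry["role"] == "primary"
        assert entry["md5"] == compute_md5(hello_result.outdir / "hello.txt")
        assert entry["size"] == len("Hello World\n")

    def test_failing_script_leaves_no_sidecars(self, tmp_path):
        recipe = make_recipe(
            "echo oops >&2\nexit 3\n", [], [OutputSpec("out", "*.txt")], name="boom"
        )
        with pytest.raises(EvaluationError) as exc:
            evaluate(recipe, {}, tmp_path / "out")
        assert exc.value.exit_code == 3
        assert "oops" in exc.value.stderr
        assert not list((tmp_path / "out").glob("*.yml"))

    def test_unmatched_primary_glob(self, tmp_path):
        recipe = make_recipe(
            "true\n", [], [OutputSpec("out", "*.vcf")], name="silent"
        )
        with pytest.raises(OutputCollectionError, match=r"\*\.vcf"):
            evaluate(recipe, {}, tmp_path / "out")
        assert not (tmp_path / "out" / "silent.yml").exists()

    def test_script_litter_not_promoted(self, tmp_path):
        recipe = make_recipe(
            "echo keep > keep.txt\necho junk > junk.log\n",
            [],
            [OutputSpec("out", "*.txt")],
            name="tidy",
        )
        result = evaluate(recipe, {}, tmp_path / "out")
        assert [p.name for p in result.data_files] == ["keep.txt"]
        assert not (tmp_path / "out" / "junk.log").exists()

    def test_collision_with_different_parameters(self, echo_recipe, tmp_path):
        """Same prefix + different recorded params must refuse to overwrite."""
        outdir = tmp_path / "out"
        evaluate(echo_recipe, {"input": "one two", "outfile": "f"}, outdir)
        # 'one-two' sanitizes identically to 'one two'
        with pytest.raises(CollisionError):
            evaluate(echo_recipe, {"input": "one-two", "outfile": "f"}, outdir)

    def test_rerun_with_identical_parameters_overwrites(self, echo_recipe, tmp_path):
        outdir = tmp_path / "out"
        first = evaluate(echo_recipe, {"input": "hi", "outfile": "f"}, outdir)
        second = evaluate(echo_recipe, {"input": "hi", "outfile": "f"}, outdir)
        assert first.prefix == second.prefix
        assert compute_md5(first.data_files[0]) == compute_md5(second.data_files[0])

    def test_repeated_evaluation_is_deterministic(self, echo_recipe, tmp_path):
        a = evaluate(echo_recipe, {"input": "stable", "outfile": "s"}, tmp_path / "a")
        b = evaluate(echo_recipe, {"input": "stable", "outfile": "s"}, tmp_path / "b")
        assert [compute_md5(p) for p in a.data_files] == [
            compute_md5(p) for p in b.data_files
        ]
        # oracle: system md5sum agrees
        out = subprocess.run(
            ["md5sum", str(a.data_files[0])], capture_output=True, text=True
        )
        assert out.stdout.split()[0] == compute_md5(a.data_files[0])

    def test_pluggable_runner_contract(self, echo_recipe, tmp_path):
        calls = []

        def stub(script, workdir, spec):
            calls.append(spec.mode)
            return subprocess.run(
                ["sh", "-e", str(script)], cwd=workdir, capture_output=True, text=True
            ).returncode, ""

        register_runner("conda-wrapped", stub)
        result = evaluate(
            echo_recipe,
            {"input": "via stub", "outfile": "v"},
            tmp_path / "out",
            runner=RunnerSpec(mode="conda-wrapped"),
        )
        assert calls == ["conda-wrapped"]
        assert result.exit_code == 0

    def test_nested_output_paths_preserved(self, tmp_path):
        recipe = make_recipe(
            "mkdir -p idx\necho a > idx/part1\necho b > idx/part2\n",
            [],
            [OutputSpec("index", "idx/*")],
            name="nested",
        )
        result = evaluate(recipe, {}, tmp_path / "out")
        assert sorted(p.name for p in result.data_files) == ["part1", "part2"]
        assert (tmp_path / "out" / "idx" / "part1").exists()


class TestCollectOutputs:
    @pytest.fixture()
    def scratch(self, tmp_path):
        for name in ("a.txt", "b.txt", "c.log"):
            (tmp_path / name).write_text(name)
        return tmp_path

    def test_glob_matches_sorted(self, scratch):
        hits = collect_outputs(scratch, [OutputSpec("out", "*.txt")])
        assert [(str(p), r) for p, r in hits] == [
            ("a.txt", "primary"),
            ("b.txt", "primary"),
        ]

    def test_empty_match_contributes_nothing(self, scratch):
        assert collect_outputs(scratch, [OutputSpec("out", "*.vcf")]) == []

    def test_overlapping_globs_report_per_spec(self, scratch):
        hits = collect_outputs(
            scratch,
            [OutputSpec("txt", "*.txt"), OutputSpec("a", "a.*", role="secondary")],
        )
        names = [str(p) for p, _ in hits]
        assert names == ["a.txt", "b.txt", "a.txt"]
        # brute-force set comparison of the union
        assert set(names) == {
            str(p.relative_to(scratch))
            for p in list(scratch.glob("*.txt")) + list(scratch.glob("a.*"))
        }


class TestChecksums:
    def test_md5_matches_system_md5sum(self, tmp_path):
        for content in (b"", b"Hello World\n"):
            f = tmp_path / "f"
            f.write_bytes(content)
            system = subprocess.run(
                ["md5sum", str(f)], capture_output=True, text=True
            ).stdout.split()[0]
            assert compute_md5(f) == system

    def test_manifest_format_and_md5sum_c(self, tmp_path):
        f = tmp_path / "data.txt"
        f.write_text("payload\n")
        manifest = write_md5_manifest([f], tmp_path / "data.md5")
        line = manifest.read_text().rstrip("\n")
        digest, name = line.split("  ")  # exactly two spaces
        assert len(digest) == 32 and name == "data.txt"
        check = subprocess.run(
            ["md5sum", "-c", manifest.name], cwd=tmp_path, capture_output=True
        )
        assert check.returncode == 0

    def test_empty_manifest(self, tmp_path):
        manifest = write_md5_manifest([], tmp_path / "empty.md5")
        assert manifest.read_text() == ""


class TestVerify:
    def test_fresh_evaluation_passes(self, hello_record):
        report = verify(hello_record)
        assert report.ok and len(report.checks) == 1

    def test_flipped_byte_fails_exactly_that_file(self, tmp_path):
        recipe = make_recipe(
            "echo one > one.txt\necho two > two.txt\n",
            [],
            [OutputSpec("out", "*.txt")],
            name="pair",
        )
        result = evaluate(recipe, {}, tmp_path / "out")
        victim = result.outdir / "one.txt"
        raw = bytearray(victim.read_bytes())
        raw[0] ^= 0xFF
        victim.write_bytes(bytes(raw))
        report = verify(DataRecord.from_sidecar(result.sidecars["yml"]))
        failures = {c.path.name: c.reason for c in report.failures}
        assert failures == {"one.txt": "checksum-mismatch"}

    def test_deleted_file_reports_missing(self, hello_result, hello_record):
        (hello_result.outdir / "hello.txt").unlink()
        report = verify(hello_record)
        assert [c.reason for c in report.failures] == ["missing"]


def test_prefix_uses_declaration_order_and_sanitization(echo_recipe):
    resolved = resolve_bindings(
        echo_recipe, {"input": "Hello World", "outfile": "hello"}
    )
    assert sidecar_prefix(echo_recipe, resolved) == "echo_out_Hello-World_hello"


def test_prefix_for_file_params_uses_basename():
    recipe = make_recipe(
        "wc -l {{table}} > n.txt\n",
        [ParameterSpec("table", ptype="file")],
        [OutputSpec("out", "*.txt")],
        name="count",
    )
    resolved = resolve_bindings(recipe, {"table": "/data/ref/genes.gtf"})
    assert sidecar_prefix(recipe, resolved) == "count_genes.gtf"
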