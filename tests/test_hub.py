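"""Recipe and data hubs: sync, keyword search, tags, persistence."""

import random

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from recipekit import (
    DataIndex,
    NotFoundError,
    RecipeIndex,
    data_search,
    data_update,
    evaluate,
    recipe_search,
    recipe_update,
    set_tags,
)
from recipekit.fixtures import make_toy_data_tree


class TestRecipeHub:
    def test_sync_counts_and_idempotence(self, catalog_dir, tmp_path):
        index = RecipeIndex(tmp_path / "cache")
        recipe_update(index, catalog_dir)
        assert len(index) == 15
        recipe_update(index, catalog_dir)
        assert len(index) == 15  # idempotent

    def test_malformed_file_reported_not_fatal(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        (src / "good.yaml").write_text(
            "name: good\nversion: 1.0.0\nscript: echo hi > o.txt\n"
            "outputs:\n- name: out\n  glob: '*.txt'\n  role: primary\n"
        )
        (src / "bad.yaml").write_text("name: [\n")
        index = recipe_update(RecipeIndex(tmp_path / "cache"), src)
        assert len(index) == 1
        assert [p for p, _ in index.last_report] == [str(src / "bad.yaml")]

    def test_unreadable_source_raises(self, tmp_path):
        from recipekit import SyncError

        with pytest.raises(SyncError):
            recipe_update(RecipeIndex(tmp_path / "cache"), tmp_path / "nope")

    def test_gencode_keyword(self, recipe_index):
        names = [r.name for r in recipe_search(recipe_index, ["gencode"])]
        assert names == [
            "gencode_annotation",
            "gencode_genome_grch38",
            "gencode_transcripts",
        ]

    def test_gatk_keyword(self, recipe_index):
        names = [r.name for r in recipe_search(recipe_index, ["gatk"])]
        assert names == [
            "gcp_broad_gatk_hg19",
            "gcp_broad_gatk_hg38",
            "gcp_gatk_mutect2_b37",
            "gcp_gatk_mutect2_hg38",
        ]

    def test_empty_keywords_return_all_sorted(self, recipe_index):
        names = [r.name for r in recipe_search(recipe_index, [])]
        assert names == sorted(names) and len(names) == 15

    def test_no_match(self, recipe_index):
        assert recipe_search(recipe_index, ["zzz-nonexistent"]) == []

    def test_higher_version_wins_with_warning(self, tmp_path):
        src = tmp_path / "src"
        src.mkdir()
        body = (
            "version: {v}\nscript: echo hi > o.txt\n"
            "outputs:\n- name: out\n  glob: '*.txt'\n  role: primary\n"
        )
        (src / "r.yaml").write_text("name: r\n" + body.format(v="2.0.0"))
        index = recipe_update(RecipeIndex(tmp_path / "cache"), src)
        (src / "r.yaml").write_text("name: r\n" + body.format(v="1.0.0"))
        with pytest.warns(UserWarning, match="keeping"):
            recipe_update(index, src)
        assert index.get("r").version == "2.0.0"

    def test_persist_reload_equivalence(self, recipe_index):
        reloaded = RecipeIndex.load(recipe_index.cache_dir)
        assert reloaded == recipe_index


class TestDataHub:
    def test_recursive_scan_depth(self, tmp_path, echo_recipe):
        evaluate(echo_recipe, {"input": "a", "outfile": "a"}, tmp_path / "d1")
        deep = tmp_path / "d1" / "d2" / "d3"
        evaluate(echo_recipe, {"input": "b", "outfile": "b"}, deep)
        index = data_update(DataIndex(tmp_path / "cache"), tmp_path / "d1")
        assert len(index) == 2
        data_update(index, tmp_path / "d1")
        assert len(index) == 2  # idempotent

    def test_missing_data_flagged(self, hello_result, tmp_path):
        (hello_result.outdir / "hello.txt").unlink()
        index = data_update(DataIndex(tmp_path / "cache"), hello_result.outdir)
        (record,) = index.records.values()
        assert record.flags == ["missing-data"]

    def test_malformed_sidecar_skipped_with_report(self, hello_result, tmp_path):
        (hello_result.outdir / "stray.yml").write_text("not: [a sidecar\n")
        index = data_update(DataIndex(tmp_path / "cache"), hello_result.outdir)
        assert len(index) == 1
        assert len(index.last_report) == 1

    def test_evaluate_then_update_closure(self, tmp_path, echo_recipe):
        """Evaluating into a scanned root adds exactly one record whose
        params equal the bindings used."""
        root = tmp_path / "root"
        index = data_update(DataIndex(tmp_path / "cache"), root.parent)
        before = len(index)
        bindings = {"input": "fresh payload", "outfile": "fresh"}
        evaluate(echo_recipe, bindings, root)
        data_update(index, root.parent)
        assert len(index) == before + 1
        (record,) = [
            r for r in index.records.values() if r.recipe_name == "echo_out"
        ]
        assert record.params == bindings

    def test_accessors(self, hello_record, hello_result):
        assert hello_record.names == ["hello.txt"]
        assert hello_record.notes == ["greeting", "demo data"]
        assert hello_record.params == {"input": "Hello World", "outfile": "hello"}
        assert hello_record.paths == [hello_result.outdir / "hello.txt"]
        assert hello_record.tags == []
        assert hello_record.yml == hello_result.sidecars["yml"]


class TestDataSearch:
    @pytest.fixture()
    def notes_index(self, tmp_path, echo_recipe):
        index = DataIndex(tmp_path / "cache")
        for i, notes in enumerate(
            (["human genome"], ["mouse genome"], ["liftover"])
        ):
            out = tmp_path / f"r{i}"
            evaluate(
                echo_recipe, {"input": f"v{i}", "outfile": f"f{i}"}, out, notes=notes
            )
            data_update(index, out)
        return index

    def test_or_of_one_keyword(self, notes_index):
        assert len(data_search(notes_index, ["genome"])) == 2

    def test_and_semantics(self, notes_index):
        hits = data_search(notes_index, ["genome", "human"])
        assert len(hits) == 1
        assert hits[0].notes == ["human genome"]

    def test_empty_keywords_return_all(self, notes_index):
        assert len(data_search(notes_index, [])) == 3

    @given(extra=st.text(min_size=1, max_size=6))
    @settings(
        max_examples=40,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_and_monotonicity(self, notes_index, extra):
        base = data_search(notes_index, ["genome"])
        narrowed = data_search(notes_index, ["genome", extra])
        assert {r.id for r in narrowed} <= {r.id for r in base}

    def test_agrees_with_brute_force_oracle(self, tmp_path):
        make_toy_data_tree(tmp_path / "tree", 20, seed=11)
        index = data_update(DataIndex(tmp_path / "cache"), tmp_path / "tree")
        assert len(index) == 20
        vocab = ["human", "genome", "lift", "payload", "echo", "zzz", "ann", "0"]
        rng = random.Random(7)
        for _ in range(100):
            keywords = rng.sample(vocab, rng.randint(1, 3))
            got = {r.id for r in data_search(index, keywords)}
            # independent linear scan over the sidecar-derived fields
            expect = set()
            for rid, rec in index.records.items():
                blob = " ".join(
                    [rec.recipe_name]
                    + rec.names
                    + rec.notes
                    + rec.tags
                    + [f"{k}={v}" for k, v in rec.params.items()]
                ).lower()
                if all(k.lower() in blob for k in keywords):
                    expect.add(rid)
            assert got == expect, keywords


class TestTags:
    def test_tag_and_search(self, tmp_path, echo_recipe):
        index = DataIndex(tmp_path / "cache")
        for i in range(3):
            evaluate(
                echo_recipe, {"input": f"v{i}", "outfile": f"f{i}"}, tmp_path / "d"
            )
        data_update(index, tmp_path / "d")
        ids = sorted(index.records)[:2]
        set_tags(index, ids, ["bwa"])
        assert {r.id for r in data_search(index, ["bwa"])} == set(ids)

    def test_retag_idempotent_and_durable(self, hello_record, tmp_path):
        index = DataIndex(tmp_path / "cache")
        data_update(index, hello_record.yml.parent)
        rid = next(iter(index.records))
        set_tags(index, [rid], ["star", "star"])
        set_tags(index, [rid], ["star"])
        assert index.get(rid).tags == ["star"]
        # tags live in the sidecar: a fresh index built from disk sees them
        fresh = data_update(DataIndex(tmp_path / "cache2"), hello_record.yml.parent)
        assert next(iter(fresh.records.values())).tags == ["star"]

    def test_unknown_id_raises(self, tmp_path):
        with pytest.raises(NotFoundError, match="ghost"):
            set_tags(DataIndex(tmp_path / "cache"), ["ghost"], ["x"])


def test_data_index_persist_reload_equivalence(tmp_path):
    make_toy_data_tree(tmp_path / "tree", 4, seed=2)
    index = data_update(DataIndex(tmp_path / "cache"), tmp_path / "tree")
    reloaded = DataIndex.load(tmp_path / "cache")
    assert reloaded == index
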