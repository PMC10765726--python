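import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for cwl_check helper

from recipekit import DataRecord, RecipeIndex, evaluate, recipe_update
from recipekit.fixtures import echo_out_recipe, make_catalog


@pytest.fixture(scope="session")
def echo_recipe():
    return echo_out_recipe()


@pytest.fixture(scope="session")
def catalog_dir(tmp_path_factory):
    dest = tmp_path_factory.mktemp("catalog")
    make_catalog(dest)
    return dest


@pytest.fixture(scope="session")
def recipe_index(catalog_dir, tmp_path_factory):
    cache = tmp_path_factory.mktemp("recipe-cache")
    return recipe_update(RecipeIndex(cache), catalog_dir)


@pytest.fixture()
def hello_result(echo_recipe, tmp_path):
    """One completed echo_out evaluation in a fresh outdir."""
    return evaluate(
        echo_recipe,
        {"input": "Hello World", "outfile": "hello"},
        tmp_path / "curated",
        notes=["greeting", "demo data"],
    )


@pytest.fixture()
def hello_record(hello_result):
    return DataRecord.from_sidecar(hello_result.sidecars["yml"])
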