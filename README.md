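# recipekit

Reproducible **data recipes** for curated genomic data: turn ad hoc
preprocessing shell scripts into parameterized, CWL-backed recipes; evaluate
them to produce curated data files with full provenance; then index, search,
tag, verify, export and remotely fetch those files for reuse in downstream
tools and workflows.

## The problem

Bioinformaticians working across projects repeatedly re-derive the same
curated resources — reference genomes and their index files, GENCODE
annotation, liftover chains, GATK bundles — from one-off scripts that are
rarely reproducible and never annotated. recipekit standardizes that work
into three layers:

1. **Recipes** (`recipekit.recipe`) — a shell script template with
   `{{param}}` placeholders, typed parameters (`string`, `int`, `float`,
   `boolean`, `file`), output extraction globs (primary data vs secondary
   companions such as `.fai`/`.dict` indexes) and declared software
   requirements. One recipe may drive multiple tools in one script. Each
   recipe also compiles to a CWL v1.2 `CommandLineTool` document
   (`recipekit.cwl`), its portable form.
2. **Evaluation** (`recipekit.evaluator`) — render the script, run it in a
   scratch directory, promote only glob-matched files, and write four
   provenance sidecars next to the data, sharing one prefix:
   `.yml` (standardized annotations: recipe, parameters, date, origin,
   per-file MD5 and size, notes, tags), `.sh` (the exact rendered script),
   `.cwl` (the CWL wrapper) and `.md5` (a GNU `md5sum -c`-compatible
   checksum manifest). A failed run writes no sidecars at all.
3. **Reuse** (`recipekit.hub`, `recipekit.exporter`) — persistent,
   keyword-searchable catalogs of recipes and of curated data (built by
   recursively scanning `.yml` sidecars), mutable tags written back into
   sidecars, checksum verification, export of record sets as CWL/WDL-style
   job-input documents (`{class: File, path: ...}` with `secondaryFiles`),
   and verified fetch of pre-built data from a bucket manifest.

The package ships a catalog of fifteen pre-built recipes (GENCODE, Ensembl
liftover, UCSC tables, GATK bundles, bowtie2/hisat2/salmon/STAR index
builders, a samtools+picard+bwa reference-genome pipeline, and the offline
`echo_out` demonstration recipe) plus deterministic offline fixtures — a
seeded toy data tree and a mock bucket — so everything is exercisable with
zero network access (`recipekit.fixtures`).

## Worked example

```python
from pathlib import Path
import recipekit as rk
from recipekit.fixtures import make_catalog, echo_out_recipe

ws = Path("demo")

# 1. sync the shipped catalog into a recipe hub and search it
make_catalog(ws / "recipes")
idx = rk.recipe_update(rk.RecipeIndex(ws / "cache"), ws / "recipes")
print([r.name for r in rk.recipe_search(idx, ["gencode"])])
# ['gencode_annotation', 'gencode_genome_grch38', 'gencode_transcripts']

# 2. evaluate the offline recipe
res = rk.evaluate(echo_out_recipe(),
                  {"input": "Hello World", "outfile": "hello"},
                  ws / "curated", notes=["greeting"])
print(res.prefix)                      # echo_out_Hello-World_hello
print(sorted(p.name for p in res.outdir.iterdir()))
# ['echo_out_Hello-World_hello.cwl', 'echo_out_Hello-World_hello.md5',
#  'echo_out_Hello-World_hello.sh', 'echo_out_Hello-World_hello.yml',
#  'hello.txt']

# 3. index, verify and export
di = rk.data_update(rk.DataIndex(ws / "cache"), ws / "curated")
rec = rk.data_search(di, ["hello"])[0]
print(rk.verify(rec).ok)               # True
doc = rk.to_workflow_inputs([rec], {rec.id: "greeting"}, format="json")
print(doc.serialize())
# {
#   "greeting": {
#     "class": "File",
#     "path": ".../demo/curated/hello.txt"
#   }
# }
```

`hello.txt` contains `Hello World`; the `.yml` sidecar records the recipe
name/version, both parameter values, an ISO-8601 UTC date, per-file MD5
digests and the `greeting` note, which is what the keyword search matched.
The same workflow is available from the shell:

```sh
recipekit fixtures init demo --seed 1
recipekit run demo/recipes/echo_out.yaml -p "input=Hello World" \
    -p outfile=hello -o demo/curated --note greeting
recipekit data update demo/curated --cache demo/cache
recipekit data search hello --cache demo/cache
```

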