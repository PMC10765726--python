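# Methods

## The recipe model

A data recipe is the unit of reproducible curation: a POSIX shell script
template plus the metadata needed to re-run it anywhere — typed parameters,
output extraction patterns, and software requirements. The design
assumption is that real curation work is script-shaped (download, unzip,
index, reformat — often several tools in sequence), so the recipe wraps
*one whole script*, not one tool per step. The CWL rendering preserves
this: the script is embedded via `InitialWorkDirRequirement` and executed
with `sh script.sh`, parameters are documented as typed CWL inputs, and
the multi-tool pipeline stays a single `CommandLineTool`. Recipes never
form DAGs.

### Placeholders and escaping

Placeholders use `{{name}}` syntax, chosen so templates can contain
ordinary shell `$var` references untouched. Names match
`[A-Za-z_][A-Za-z0-9_]*`. Construction cross-checks template and
declaration both ways: an undeclared `{{token}}` and a declared-but-unused
parameter are both errors, reported together.

Bound values are substituted after backslash-escaping the four characters
that can break out of a double-quoted shell word (`\`, `"`, `` ` ``, `$`).
This was a genuine design choice: whole-word quoting (shlex-style
single-quoting) is safer in unquoted positions but would corrupt the
common idiom where the template already quotes the placeholder
(`echo "{{input}}"` must render `echo "Hello World"`, not
`echo "'Hello World'"`). The chosen scheme keeps simple values verbatim,
makes hostile values inert inside double-quoted contexts, and is verified
by a property test that round-trips rendered commands through a real shell
(using `printf '%s'` as the probe, since `echo` interprets backslashes
itself). The residual obligation on recipe authors is to double-quote
placeholders whose values may contain whitespace — the same obligation
shell itself imposes.

### Types and coercion

Parameter types are `string`, `int`, `float`, `boolean`, `file`. Because
CLI bindings arrive as text, numeral strings coerce to int/float and
`"true"`/`"false"` (case-insensitive) to boolean; `bool` is deliberately
rejected where an int is expected. Optional parameters must declare a
default, which fills in at resolution time. Booleans render into scripts
as `true`/`false` (valid shell commands as well as readable flags).

## Evaluation and provenance

Evaluation runs the rendered script with `sh -e` in a throwaway scratch
directory, then *promotes* only files matched by the recipe's output globs
into the destination — script litter (logs, temp files) never reaches the
curated directory. Primary globs must match at least one file; secondary
globs may match none. Files matched by several globs are recorded once,
with the role of the first (declaration-order) spec that matched.

The four sidecars (`.yml`, `.sh`, `.cwl`, `.md5`) share a prefix built
from the recipe name plus the sanitized parameter values in declaration
order (`echo_out_Hello-World_hello`); `file`-typed values contribute their
basename. Sanitization maps anything outside `[A-Za-z0-9._-]` to `-`,
which makes prefixes filesystem-safe but not injective — therefore a
pre-existing `.yml` with the same prefix but *different* recorded
parameters is a hard collision error, while identical parameters overwrite
(a re-run). Failure at any stage (script exit ≠ 0, unmatched primary glob)
writes no sidecars, so an index scan can never observe half-curated data.

Checksums are MD5, matching the `.md5` manifest convention
(`<digest>  <name>`, GNU `md5sum -c`-compatible); the role of the digest
here is integrity/change detection, not cryptographic authentication.
Timestamps are ISO-8601 UTC with seconds precision. Runner backends are
pluggable behind `RunnerSpec` (`direct-shell` is built in;
`conda-wrapped`/`cwl-engine` hooks must honor the same contract), keeping
environment provisioning orthogonal to the evaluation algorithm.

## Indexes and search

The recipe hub syncs `*.yaml` files from source directories (remote
transports plug in the same way); invalid files are reported, not fatal.
One version per recipe name is kept; the higher semantic version wins,
with a warning. The data hub scans roots recursively for `.yml` sidecars;
records with vanished data files are indexed but flagged `missing-data`.

Search is case-insensitive substring match, AND-combined across keywords —
AND because narrowing is the common retrieval need, and it gives the
useful monotonicity property (adding a keyword never enlarges results).
The data-side haystack is recipe name + data file basenames + notes + tags
+ `key=value` stringified parameters; including parameters means a search
for `GRCh38` finds data curated *for* GRCh38 even when the filename hides
it. Both indexes persist as one JSON file per cache directory; the
contract (asserted in tests) is that persist→reload yields an equal index.
Tags are written through to the sidecar, which is authoritative: tags must
survive a rescan and travel with a shared data folder.

## Export and remote fetch

Exports follow the CWL job-input convention — each record's primary file
becomes `{class: File, path: <abs>}`, recorded secondary files populate
`secondaryFiles` — serialized as JSON or YAML; the same shape is consumed
by WDL engines and is trivially parseable by anything else. The bucket
manifest is a TSV (`recipe, params_json, path, md5, size`) with parameters
in canonical JSON (sorted keys) so (recipe, params) lookup is exact.
Fetches verify the manifest digest; a mismatch quarantines the payload
under a `.corrupt` suffix rather than deleting evidence. A fetched file
gets a synthetic sidecar (origin = bucket base, version `unknown` — the
manifest carries no version) so it indexes and searches exactly like a
local evaluation, differing only in origin and date. No compatibility with
any particular cloud provider's object layout is claimed.

## Fixtures: what they emulate and what they do not

The shipped fifteen-recipe catalog reproduces realistic curation metadata
(true upstream origin URLs, plausible multi-tool scripts, secondary-file
patterns), but the network-dependent recipes are only schema-validated and
CWL-rendered in tests — never executed. Executable coverage comes from
`echo_out` and purpose-built toy recipes, whose outputs are tiny text
files. Passing tests therefore demonstrate the *mechanics* — templating,
escaping, output collection, sidecar integrity, indexing, fetch — on
deterministic data; they do not exercise large files, slow downloads,
flaky networks, or the real tools (samtools, STAR, GATK) the catalog
scripts name. Toy trees and mock buckets are generated from a seed
(`random.Random(seed)`), byte-reproducible except for evaluation
timestamps.

## Numerical and procedural choices

- Problem sizes: the search-correctness checks use a 20-record seeded tree
  and 100 random keyword sets against a brute-force linear-scan oracle;
  byte-flip detection flips every byte of the probe file in turn. These
  sizes exhaust the interesting structure (group nesting, note/name/param
  overlap, hash avalanche) while keeping the whole suite in seconds.
- CWL validity is checked by an independent structural validator written
  for the test suite (type vocabulary, glob-bound File outputs,
  requirement shapes, map/list forms); it shares no code with the
  renderer and is itself negative-tested against mangled documents.
- YAML output uses literal block style for multi-line scripts and
  caller-order keys; write→read→write is byte-identical by construction.
- Record ids are the first 12 hex digits of the MD5 of the sidecar's
  absolute path: stable across rescans on one machine, cheap to compute,
  and collision-safe at any realistic catalog size.

## Known limitations

- Quoting guarantees apply to placeholders in double-quoted (or quoted)
  positions; an unquoted placeholder with a whitespace-containing value
  splits, as in plain shell.
- The index is last-write-wins; no multi-writer locking.
- `conda-wrapped` and `cwl-engine` runners are contract hooks, not
  implementations; direct-shell assumes required tools are on PATH.
- Record identity is path-based: moving a sidecar changes its id (the
  content, including tags, is unaffected).
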