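"""Hand curated data to downstream tools, and fetch pre-built data remotely.

Two jobs live here:

* **export** — turn a set of indexed data records into a workflow job-input
  document (JSON or YAML) following the CWL convention: each primary data
  file becomes ``{class: File, path: ...}`` with recorded secondary files in
  ``secondaryFiles``. The same document feeds CWL and WDL engines, or is
  simply read as a path listing by shell pipelines and R scripts.

* **fetch** — download a pre-built curated file from a "bucket": any
  location holding the data plus a TSV manifest listing, per entry, the
  recipe, its canonical-JSON parameters, the relative path, MD5 and size.
  Fetched files are checksum-verified and given a synthetic provenance
  sidecar so they index and search exactly like locally evaluated data
  (differing only in origin and date).

Transport is an injected callable ``(base, relative_path) -> bytes`` so
tests and offline use run against plain directories; HTTP(S) support plugs
in the same way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

from ._yamlio import dump_yaml, write_yaml
from .errors import ExportError, IntegrityError, ManifestError, NotFoundError
from .evaluator import SidecarMeta, compute_md5
from .hub import DataRecord

MANIFEST_COLUMNS = ("recipe", "params_json", "path", "md5", "size")
MANIFEST_NAME = "manifest.tsv"

Transport = Callable[[str, str], bytes]


def local_transport(base: str, relative: str) -> bytes:
    """Default transport: read from a local directory bucket."""
    return (Path(base) / relative).read_bytes()


def canonical_params(params: Mapping[str, Any]) -> str:
    """Canonical JSON for parameter bindings (sorted keys, no whitespace
    variance) so (recipe, params) lookup is exact."""
    return json.dumps(dict(params), sort_keys=True, separators=(",", ":"))


# ---------------------------------------------------------------------------
# workflow job-input export


@dataclass(frozen=True)
class WorkflowInputDoc:
    """A workflow job-input document (CWL/WDL job file convention)."""

    format: str  # "json" | "yaml"
    entries: dict[str, Any]

    def serialize(self) -> str:
        if self.format == "json":
            return json.dumps(self.entries, indent=2) + "\n"
        return dump_yaml(self.entries)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.serialize())
        return path


def _file_object(record: DataRecord, primary: Path) -> dict:
    obj: dict[str, Any] = {"class": "File", "path": str(primary.resolve())}
    secondaries = [str(p.resolve()) for p in record.secondary_paths]
    if secondaries:
        obj["secondaryFiles"] = [
            {"class": "File", "path": p} for p in secondaries
        ]
    return obj


def to_workflow_inputs(
    records: Sequence[DataRecord],
    key_map: Mapping[str, str],
    format: str = "json",
    allow_missing: bool = False,
) -> WorkflowInputDoc:
    """Build a job-input document from data records.

    ``key_map`` maps record id to the workflow input name. Each record's
    primary file becomes a CWL File object (a list of them if the record
    has several primaries); recorded secondary files populate
    ``secondaryFiles``. Entries are ordered by input name.
    """
    if format not in ("json", "yaml"):
        raise ExportError(f"unsupported format: {format!r}")
    missing_keys = [r.id for r in records if r.id not in key_map]
    if missing_keys:
        raise ExportError(f"key_map does not cover record ids: {missing_keys}")
    names = [key_map[r.id] for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ExportError(f"duplicate input names: {dupes}")

    entries: dict[str, Any] = {}
    for record in records:
        if not allow_missing:
            for path in record.paths:
                if not path.exists():
                    raise ExportError(f"data file missing: {path}")
        primaries = record.primary_paths
        objs = [_file_object(record, p) for p in primaries]
        entries[key_map[record.id]] = objs[0] if len(objs) == 1 else objs
    return WorkflowInputDoc(format=format, entries=dict(sorted(entries.items())))


def default_key_map(records: Sequence[DataRecord]) -> dict[str, str]:
    """Derive unique input names from primary-file stems (``name``,
    ``name_2``, ...)."""
    key_map: dict[str, str] = {}
    used: dict[str, int] = {}
    for record in records:
        stem = record.primary_paths[0].stem if record.primary_paths else record.id
        n = used.get(stem, 0) + 1
        used[stem] = n
        key_map[record.id] = stem if n == 1 else f"{stem}_{n}"
    return key_map


# ---------------------------------------------------------------------------
# remote bucket


@dataclass(frozen=True)
class BucketEntry:
    recipe_name: str
    params: dict[str, Any]
    path: str
    md5: str
    size: int


@dataclass(frozen=True)
class BucketManifest:
    base: str
    entries: tuple[BucketEntry, ...]

    def find(self, recipe_name: str, params: Mapping[str, Any]) -> BucketEntry | None:
        wanted = canonical_params(params)
        for entry in self.entries:
            if (
                entry.recipe_name == recipe_name
                and canonical_params(entry.params) == wanted
            ):
                return entry
        return None


def read_manifest(
    location: str | Path, transport: Transport | None = None
) -> BucketManifest:
    """Parse a bucket manifest TSV.

    ``location`` is the manifest file itself; its parent directory (or URL
    prefix) becomes the bucket base. Header must be
    ``recipe<TAB>params_json<TAB>path<TAB>md5<TAB>size``.
    """
    location = str(location)
    base, _, name = location.rpartition("/")
    if not base:
        base = "."
    transport = transport or local_transport
    text = transport(base, name).decode()
    lines = text.splitlines()
    if not lines:
        raise ManifestError("empty manifest: missing header")
    header = tuple(lines[0].split("\t"))
    if header != MANIFEST_COLUMNS:
        raise ManifestError(
            f"bad manifest header: {header!r}, expected {MANIFEST_COLUMNS!r}"
        )
    entries: list[BucketEntry] = []
    seen_paths: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ManifestError(f"manifest line {lineno}: expected 5 fields")
        recipe, params_json, path, md5, size = fields
        try:
            params = json.loads(params_json)
        except json.JSONDecodeError as exc:
            raise ManifestError(
                f"manifest line {lineno}: bad params JSON: {exc}"
            ) from exc
        if len(md5) != 32 or any(c not in "0123456789abcdef" for c in md5):
            raise ManifestError(f"manifest line {lineno}: bad md5 {md5!r}")
        if path in seen_paths:
            raise ManifestError(f"manifest line {lineno}: duplicate path {path!r}")
        seen_paths.add(path)
        entries.append(
            BucketEntry(
                recipe_name=recipe,
                params=params,
                path=path,
                md5=md5,
                size=int(size),
            )
        )
    return BucketManifest(base=base, entries=tuple(entries))


def _fetched_prefix(recipe_name: str, params: Mapping[str, Any]) -> str:
    from .evaluator import _sanitize  # shared sanitizer, single definition

    parts = [recipe_name]
    for key in sorted(params):
        parts.append(_sanitize(str(params[key])))
    return "_".join(parts)


def fetch_remote(
    manifest: BucketManifest,
    recipe_name: str,
    params: Mapping[str, Any],
    dest: str | Path,
    transport: Transport | None = None,
) -> DataRecord:
    """Fetch one pre-built curated file and register it locally.

    The file is copied into ``dest``, its MD5 verified against the
    manifest (a mismatch quarantines the payload with a ``.corrupt``
    suffix), and a synthetic ``.yml`` sidecar is written recording the
    bucket as origin — so ``data_update`` indexes the fetch like any local
    evaluation.
    """
    transport = transport or local_transport
    entry = manifest.find(recipe_name, params)
    if entry is None:
        near = [
            canonical_params(e.params)
            for e in manifest.entries
            if e.recipe_name == recipe_name
        ]
        raise NotFoundError(
            f"no bucket entry for {recipe_name!r} with params "
            f"{canonical_params(params)}; available param sets: {near}"
        )
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    payload = transport(manifest.base, entry.path)
    target = dest / Path(entry.path).name
    target.write_bytes(payload)
    digest = compute_md5(target)
    if digest != entry.md5:
        quarantine = target.with_name(target.name + ".corrupt")
        target.rename(quarantine)
        raise IntegrityError(
            f"md5 mismatch for {entry.path!r}: manifest {entry.md5}, "
            f"got {digest}; payload quarantined at {quarantine}"
        )

    prefix = _fetched_prefix(recipe_name, entry.params)
    meta = SidecarMeta(
        recipe_name=recipe_name,
        recipe_version="unknown",
        parameters=dict(entry.params),
        date=datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
        origin=manifest.base,
        command_file="",
        outputs=[
            {
                "path": target.name,
                "role": "primary",
                "md5": entry.md5,
                "size": target.stat().st_size,
            }
        ],
        software=[],
        notes=[],
        tags=[],
    )
    yml_path = write_yaml(meta.to_dict(), dest / f"{prefix}.yml")
    return DataRecord.from_sidecar(yml_path)
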