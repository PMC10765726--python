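"""Persistent catalogs of recipes and curated data, with keyword search.

Two caching systems mirror the two halves of the workflow:

* a **recipe hub** (:class:`RecipeIndex`) synchronized from directories of
  recipe YAML files — the shared, versioned library of curation procedures;
* a **data hub** (:class:`DataIndex`) built by recursively scanning a data
  root for ``.yml`` provenance sidecars — the catalog of datasets already
  curated on this machine (or fetched from a bucket) and ready for reuse.

Both persist as a single JSON file in their cache directory and reload to
an equal index. Search is case-insensitive substring match, AND-combined
across keywords: adding a keyword can only narrow the result set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

from ._yamlio import read_yaml, write_yaml
from .errors import NotFoundError, RecipeKitError, SyncError
from .evaluator import SidecarMeta
from .recipe import Recipe, read_recipe

RECIPE_INDEX_FILE = "recipe_index.json"
DATA_INDEX_FILE = "data_index.json"


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _version_key(version: str) -> tuple:
    parts = []
    for token in version.replace("-", ".").replace("+", ".").split("."):
        parts.append((0, int(token)) if token.isdigit() else (1, token))
    return tuple(parts)


# ---------------------------------------------------------------------------
# recipe hub


@dataclass
class RecipeEntry:
    recipe: Recipe
    source_path: Path
    synced_at: str

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RecipeEntry)
            and self.recipe == other.recipe
            and Path(self.source_path) == Path(other.source_path)
        )


class RecipeIndex:
    """Keyword-searchable catalog of recipe definitions."""

    def __init__(self, cache_dir: str | Path):
        self.cache_dir = Path(cache_dir)
        self.entries: dict[str, RecipeEntry] = {}
        self.sources: list[str] = []
        self.last_report: list[tuple[str, str]] = []  # (file, problem)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, RecipeIndex) and self.entries == other.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def get(self, name: str) -> Recipe:
        if name not in self.entries:
            raise NotFoundError(f"no recipe named {name!r} in index")
        return self.entries[name].recipe

    def save(self) -> Path:
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "sources": self.sources,
            "entries": {
                name: {
                    "source": str(e.source_path),
                    "synced_at": e.synced_at,
                }
                for name, e in sorted(self.entries.items())
            },
        }
        path = self.cache_dir / RECIPE_INDEX_FILE
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, cache_dir: str | Path) -> "RecipeIndex":
        index = cls(cache_dir)
        path = index.cache_dir / RECIPE_INDEX_FILE
        if not path.exists():
            return index
        payload = json.loads(path.read_text())
        index.sources = list(payload.get("sources", []))
        for name, meta in payload.get("entries", {}).items():
            source = Path(meta["source"])
            try:
                recipe = read_recipe(source)
            except (OSError, RecipeKitError) as exc:
                index.last_report.append((str(source), str(exc)))
                continue
            index.entries[name] = RecipeEntry(recipe, source, meta["synced_at"])
        return index


def recipe_update(index: RecipeIndex, source: str | Path) -> RecipeIndex:
    """Synchronize recipe files from a source directory into the index.

    Every ``*.yaml`` file under ``source`` (recursively) is parsed and
    upserted by recipe name; invalid files are collected in
    ``index.last_report`` rather than aborting the sync. When a name is
    already present, the higher semantic version wins (with a warning on
    downgrade attempts).
    """
    source = Path(source)
    if not source.is_dir():
        raise SyncError(f"recipe source is not a readable directory: {source}")
    report: list[tuple[str, str]] = []
    stamp = _now()
    for path in sorted(source.rglob("*.yaml")):
        try:
            recipe = read_recipe(path)
        except RecipeKitError as exc:
            report.append((str(path), str(exc)))
            continue
        existing = index.entries.get(recipe.name)
        if existing is not None and existing.recipe != recipe:
            if _version_key(recipe.version) < _version_key(existing.recipe.version):
                warnings.warn(
                    f"recipe {recipe.name!r}: keeping version "
                    f"{existing.recipe.version} over older {recipe.version}",
                    stacklevel=2,
                )
                continue
            if recipe.version != existing.recipe.version:
                warnings.warn(
                    f"recipe {recipe.name!r}: replacing version "
                    f"{existing.recipe.version} with {recipe.version}",
                    stacklevel=2,
                )
        index.entries[recipe.name] = RecipeEntry(recipe, path, stamp)
    if str(source) not in index.sources:
        index.sources.append(str(source))
    index.last_report = report
    index.save()
    return index


def recipe_search(index: RecipeIndex, keywords: Sequence[str]) -> list[Recipe]:
    """Case-insensitive substring AND-search over recipe name + description.

    An empty keyword list returns every recipe. Results sort by name.
    """
    terms = [k.lower() for k in keywords if k]
    hits = []
    for name in sorted(index.entries):
        recipe = index.entries[name].recipe
        haystack = f"{recipe.name} {recipe.description}".lower()
        if all(t in haystack for t in terms):
            hits.append(recipe)
    return hits


# ---------------------------------------------------------------------------
# data hub


def record_id(yml_path: str | Path) -> str:
    """Stable record identifier derived from the sidecar's absolute path."""
    return hashlib.md5(str(Path(yml_path).resolve()).encode()).hexdigest()[:12]


@dataclass
class DataRecord:
    """One curated dataset: its sidecar, data files, and mutable tags.

    Accessor properties mirror the hub vocabulary: ``names`` (data file
    basenames), ``notes``, ``params``, ``paths``, ``tags`` and ``yml``.
    """

    id: str
    yml_path: Path
    recipe_name: str
    recipe_version: str
    params: dict[str, Any]
    notes: list[str]
    tags: list[str]
    date: str
    origin: str
    outputs: list[dict]  # {path, role, md5, size}
    flags: list[str] = field(default_factory=list)

    # -- accessors -----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [Path(o["path"]).name for o in self.outputs]

    @property
    def paths(self) -> list[Path]:
        base = Path(self.yml_path).parent
        return [base / o["path"] for o in self.outputs]

    @property
    def data_paths(self) -> list[Path]:
        return self.paths

    @property
    def primary_paths(self) -> list[Path]:
        base = Path(self.yml_path).parent
        return [base / o["path"] for o in self.outputs if o["role"] == "primary"]

    @property
    def secondary_paths(self) -> list[Path]:
        base = Path(self.yml_path).parent
        return [base / o["path"] for o in self.outputs if o["role"] == "secondary"]

    @property
    def yml(self) -> Path:
        return Path(self.yml_path)

    # -- construction --------------------------------------------------
    @classmethod
    def from_sidecar(cls, yml_path: str | Path) -> "DataRecord":
        yml_path = Path(yml_path)
        meta = SidecarMeta.from_dict(read_yaml(yml_path))
        record = cls(
            id=record_id(yml_path),
            yml_path=yml_path,
            recipe_name=meta.recipe_name,
            recipe_version=meta.recipe_version,
            params=dict(meta.parameters),
            notes=list(meta.notes),
            tags=list(meta.tags),
            date=meta.date,
            origin=meta.origin,
            outputs=[dict(o) for o in meta.outputs],
        )
        record.flags = (
            ["missing-data"] if any(not p.exists() for p in record.paths) else []
        )
        return record

    def search_text(self) -> str:
        """The haystack data_search matches against."""
        parts = [self.recipe_name]
        parts.extend(self.names)
        parts.extend(self.notes)
        parts.extend(self.tags)
        parts.extend(f"{k}={v}" for k, v in self.params.items())
        return " ".join(str(p) for p in parts).lower()

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "yml_path": str(self.yml_path),
            "recipe_name": self.recipe_name,
            "recipe_version": self.recipe_version,
            "params": self.params,
            "notes": self.notes,
            "tags": self.tags,
            "date": self.date,
            "origin": self.origin,
            "outputs": self.outputs,
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DataRecord":
        data = dict(data)
        data["yml_path"] = Path(data["yml_path"])
        return cls(**data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataRecord):
            return NotImplemented
        return self.to_dict() == other.to_dict()


class DataIndex:
    """Catalog of curated-data records found by scanning sidecar files."""

    def __init__(self, cache_dir: str | Path):
        self.cache_dir = Path(cache_dir)
        self.records: dict[str, DataRecord] = {}
        self.scanned_roots: list[str] = []
        self.last_report: list[tuple[str, str]] = []

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DataIndex)
            and self.records == other.records
            and sorted(self.scanned_roots) == sorted(other.scanned_roots)
        )

    def get(self, rid: str) -> DataRecord:
        if rid not in self.records:
            raise NotFoundError(f"no data record with id {rid!r}")
        return self.records[rid]

    def save(self) -> Path:
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "scanned_roots": sorted(self.scanned_roots),
            "records": {
                rid: r.to_dict() for rid, r in sorted(self.records.items())
            },
        }
        path = self.cache_dir / DATA_INDEX_FILE
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, cache_dir: str | Path) -> "DataIndex":
        index = cls(cache_dir)
        path = index.cache_dir / DATA_INDEX_FILE
        if not path.exists():
            return index
        payload = json.loads(path.read_text())
        index.scanned_roots = list(payload.get("scanned_roots", []))
        index.records = {
            rid: DataRecord.from_dict(r)
            for rid, r in payload.get("records", {}).items()
        }
        return index


def data_update(index: DataIndex, root: str | Path) -> DataIndex:
    """Recursively scan ``root`` for ``.yml`` sidecars and upsert records.

    Malformed sidecars are skipped and reported in ``index.last_report``;
    records whose data files are gone are indexed but flagged
    ``missing-data``. Re-running over the same tree is idempotent.
    """
    root = Path(root)
    if not root.is_dir():
        raise SyncError(f"data root is not a readable directory: {root}")
    report: list[tuple[str, str]] = []
    for yml in sorted(root.rglob("*.yml")):
        try:
            record = DataRecord.from_sidecar(yml)
        except RecipeKitError as exc:
            report.append((str(yml), str(exc)))
            continue
        index.records[record.id] = record
    if str(root) not in index.scanned_roots:
        index.scanned_roots.append(str(root))
    index.last_report = report
    index.save()
    return index


def data_search(index: DataIndex, keywords: Sequence[str]) -> list[DataRecord]:
    """AND-combined case-insensitive substring search over each record's
    recipe name, data file basenames, notes, tags and stringified params.

    An empty keyword list returns every record. Results sort by id for
    stable output.
    """
    terms = [k.lower() for k in keywords if k]
    hits = []
    for rid in sorted(index.records):
        record = index.records[rid]
        haystack = record.search_text()
        if all(t in haystack for t in terms):
            hits.append(record)
    return hits


def set_tags(
    index: DataIndex, record_ids: Iterable[str], tags: Sequence[str]
) -> DataIndex:
    """Assign ``tags`` to the given records, durably.

    Tags are written both into the index and back into each record's
    ``.yml`` sidecar — the sidecar is authoritative, so tags survive a
    rescan and travel with the data directory.
    """
    ids = list(record_ids)
    unknown = [rid for rid in ids if rid not in index.records]
    if unknown:
        raise NotFoundError(f"unknown record ids: {unknown}")
    tags = [t for t in tags if t]
    for rid in ids:
        record = index.records[rid]
        record.tags = list(dict.fromkeys(tags))
        doc = read_yaml(record.yml_path)
        doc["tags"] = record.tags
        write_yaml(doc, record.yml_path)
    index.save()
    return index
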