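"""Recipe evaluation: run the rendered script and write provenance sidecars.

Evaluating a recipe against parameter bindings renders the script, executes
it in a scratch directory, promotes only the files matched by the recipe's
output globs into the target directory, and writes four sidecar files that
share one prefix:

``<prefix>.yml``
    standardized provenance annotations — recipe name/version, the exact
    parameter values, evaluation date, data origin, per-file MD5 digests
    and sizes, resolved software requirements, free-text notes and mutable
    tags;
``<prefix>.sh``
    the exact rendered shell script;
``<prefix>.cwl``
    the CWL CommandLineTool form of the recipe;
``<prefix>.md5``
    a GNU ``md5sum``-compatible checksum manifest (verifiable with
    ``md5sum -c``).

The prefix is the recipe name followed by the sanitized parameter values in
declaration order (``echo_out_Hello-World_hello``), which makes evaluations
with distinct parameters land side by side in one directory. A failed
evaluation writes no sidecars at all, so a half-curated dataset can never
be indexed.
"""

from __future__ import annotations

import hashlib
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

from ._yamlio import read_yaml, write_yaml
from .cwl import to_cwl, write_cwl
from .errors import (
    CollisionError,
    EvaluationError,
    OutputCollectionError,
    RecipeKitError,
)
from .recipe import (
    Bindings,
    OutputSpec,
    Recipe,
    render_script,
    render_value,
    resolve_bindings,
)

SIDECAR_EXTENSIONS = (".yml", ".sh", ".cwl", ".md5")


@dataclass(frozen=True)
class RunnerSpec:
    """How to execute the rendered script.

    ``direct-shell`` runs it with ``sh -e`` on the host. ``conda-wrapped``
    and ``cwl-engine`` are pluggable hooks (see :func:`register_runner`)
    that must honor the same contract: run the script in the given working
    directory and return (exit_code, stderr).
    """

    mode: str = "direct-shell"
    options: Mapping[str, Any] = field(default_factory=dict)


Runner = Callable[[Path, Path, RunnerSpec], tuple[int, str]]


def _run_direct_shell(script: Path, workdir: Path, spec: RunnerSpec) -> tuple[int, str]:
    shell = spec.options.get("shell", "sh")
    proc = subprocess.run(
        [shell, "-e", str(script)],
        cwd=workdir,
        capture_output=True,
        text=True,
    )
    return proc.returncode, proc.stderr


_RUNNERS: dict[str, Runner] = {"direct-shell": _run_direct_shell}


def register_runner(mode: str, runner: Runner) -> None:
    """Register an execution backend for :class:`RunnerSpec` mode ``mode``."""
    _RUNNERS[mode] = runner


@dataclass
class SidecarMeta:
    """The provenance record stored in the ``.yml`` sidecar."""

    recipe_name: str
    recipe_version: str
    parameters: dict[str, Any]
    date: str
    origin: str
    command_file: str
    outputs: list[dict]  # each: {path, role, md5, size}
    software: list[dict]
    notes: list[str]
    tags: list[str]

    def to_dict(self) -> dict:
        return {
            "recipe": self.recipe_name,
            "version": self.recipe_version,
            "params": dict(self.parameters),
            "date": self.date,
            "origin": self.origin,
            "command_file": self.command_file,
            "outputs": [dict(o) for o in self.outputs],
            "software": [dict(s) for s in self.software],
            "notes": list(self.notes),
            "tags": list(self.tags),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SidecarMeta":
        for key in ("recipe", "params", "date", "outputs"):
            if key not in data:
                raise RecipeKitError(f"sidecar missing field: {key}")
        return cls(
            recipe_name=data["recipe"],
            recipe_version=str(data.get("version", "unknown")),
            parameters=dict(data["params"] or {}),
            date=data["date"],
            origin=data.get("origin") or "local",
            command_file=data.get("command_file") or "",
            outputs=[dict(o) for o in data["outputs"]],
            software=[dict(s) for s in data.get("software") or ()],
            notes=[n for n in data.get("notes") or ()],
            tags=[t for t in data.get("tags") or ()],
        )


@dataclass
class EvaluationResult:
    outdir: Path
    prefix: str
    data_files: list[Path]
    sidecars: dict[str, Path]  # keyed "yml"/"sh"/"cwl"/"md5"
    meta: SidecarMeta
    exit_code: int


def compute_md5(path: str | Path) -> str:
    """MD5 hex digest (32 lowercase hex chars) of a file's bytes."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_md5_manifest(files: Sequence[str | Path], path: str | Path) -> Path:
    """Write a GNU coreutils ``md5sum``-format manifest.

    One ``<digest>  <name>`` line per file, two spaces between digest and
    name; names are recorded relative to the manifest's directory so that
    ``md5sum -c`` succeeds when run there.
    """
    path = Path(path)
    base = path.parent
    lines = []
    for f in files:
        f = Path(f)
        try:
            name = f.relative_to(base)
        except ValueError:
            name = f
        lines.append(f"{compute_md5(f)}  {name}")
    path.write_text("".join(line + "\n" for line in lines))
    return path


def collect_outputs(
    scratch_dir: str | Path, outputs: Iterable[OutputSpec]
) -> list[tuple[Path, str]]:
    """Match output globs under ``scratch_dir``.

    Returns ``(relative path, role)`` pairs, sorted lexicographically within
    each OutputSpec, in OutputSpec order. A file matched by several specs is
    reported once per spec; deduplication across specs is the caller's job.
    Empty matches contribute nothing (primary-glob enforcement is
    :func:`evaluate`'s responsibility).
    """
    scratch = Path(scratch_dir)
    matched: list[tuple[Path, str]] = []
    for spec in outputs:
        hits = sorted(
            p.relative_to(scratch)
            for p in scratch.glob(spec.glob)
            if p.is_file()
        )
        matched.extend((hit, spec.role) for hit in hits)
    return matched


def _sanitize(token: str) -> str:
    token = re.sub(r"[^A-Za-z0-9._-]+", "-", token).strip("-.")
    return token or "x"


def sidecar_prefix(recipe: Recipe, resolved: Mapping[str, Any]) -> str:
    """Deterministic sidecar prefix: recipe name + sanitized parameter values
    in declaration order (file parameters contribute their basename)."""
    parts = [recipe.name]
    for p in recipe.parameters:
        text = render_value(p.ptype, resolved[p.name])
        if p.ptype == "file":
            text = Path(text).name
        parts.append(_sanitize(text))
    return "_".join(parts)


def _iso_now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def evaluate(
    recipe: Recipe,
    bindings: Bindings,
    outdir: str | Path,
    notes: Sequence[str] = (),
    runner: RunnerSpec | None = None,
) -> EvaluationResult:
    """Evaluate a recipe: run its script and curate the matched outputs.

    The script runs in a temporary scratch directory; only files matched by
    the recipe's output globs are promoted into ``outdir`` (script litter
    stays behind). On success the four sidecars are written; on any failure
    nothing is (no partial success).

    Raises
    ------
    BindingError
        bindings invalid for the recipe.
    EvaluationError
        script exited non-zero (carries exit code and captured stderr).
    OutputCollectionError
        a primary glob matched no files.
    CollisionError
        ``outdir`` already holds this prefix with *different* recorded
        parameters; identical parameters overwrite.
    """
    runner = runner or RunnerSpec()
    if runner.mode not in _RUNNERS:
        raise RecipeKitError(f"unsupported runner mode: {runner.mode!r}")
    notes = [n for n in notes if n]

    resolved = resolve_bindings(recipe, bindings)
    rendered = render_script(recipe, bindings)
    prefix = sidecar_prefix(recipe, resolved)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    yml_path = outdir / f"{prefix}.yml"
    if yml_path.exists():
        prior = SidecarMeta.from_dict(read_yaml(yml_path))
        if prior.parameters != resolved:
            raise CollisionError(
                f"sidecar prefix {prefix!r} exists in {outdir} with different "
                f"parameters: {prior.parameters!r} vs {resolved!r}"
            )

    with tempfile.TemporaryDirectory(prefix="recipekit-") as scratch:
        scratch = Path(scratch)
        script_path = scratch / "script.sh"
        script_path.write_text(rendered)
        workdir = scratch / "work"
        workdir.mkdir()

        exit_code, stderr = _RUNNERS[runner.mode](script_path, workdir, runner)
        if exit_code != 0:
            raise EvaluationError(exit_code, stderr)

        matched = collect_outputs(workdir, recipe.outputs)
        # every primary glob must have matched at least one file
        for spec in recipe.outputs:
            if spec.role == "primary" and not any(
                workdir.glob(spec.glob)
            ):
                raise OutputCollectionError(spec.glob)

        # dedupe while preserving first-match role and order
        seen: dict[Path, str] = {}
        for rel, role in matched:
            seen.setdefault(rel, role)

        data_files: list[Path] = []
        out_entries: list[dict] = []
        for rel, role in seen.items():
            dest = outdir / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(workdir / rel), str(dest))
            data_files.append(dest)
            out_entries.append(
                {
                    "path": str(rel),
                    "role": role,
                    "md5": compute_md5(dest),
                    "size": dest.stat().st_size,
                }
            )

    meta = SidecarMeta(
        recipe_name=recipe.name,
        recipe_version=recipe.version,
        parameters=resolved,
        date=_iso_now(),
        origin=recipe.origin or "local",
        command_file=f"{prefix}.sh",
        outputs=out_entries,
        software=[
            {"tool": r.tool, "version": r.version, "source": r.source, "spec": r.spec}
            for r in recipe.requirements
        ],
        notes=list(notes),
        tags=[],
    )

    sh_path = outdir / f"{prefix}.sh"
    sh_path.write_text(rendered)
    cwl_path = write_cwl(to_cwl(recipe), outdir / f"{prefix}.cwl")
    md5_path = write_md5_manifest(data_files, outdir / f"{prefix}.md5")
    write_yaml(meta.to_dict(), yml_path)

    return EvaluationResult(
        outdir=outdir,
        prefix=prefix,
        data_files=data_files,
        sidecars={"yml": yml_path, "sh": sh_path, "cwl": cwl_path, "md5": md5_path},
        meta=meta,
        exit_code=0,
    )


@dataclass(frozen=True)
class FileCheck:
    path: Path
    ok: bool
    reason: str  # "ok" | "missing" | "checksum-mismatch"


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[FileCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)

    @property
    def failures(self) -> tuple[FileCheck, ...]:
        return tuple(c for c in self.checks if not c.ok)


def verify(record) -> VerificationReport:
    """Re-hash a record's data files against the digests in its sidecar.

    ``record`` is any object exposing ``yml_path`` and ``outputs`` (each
    output with ``path``/``md5``), i.e. a hub DataRecord or a SidecarMeta
    paired with its directory. Missing files are reported as failures with
    reason ``missing``, never raised.
    """
    base = Path(record.yml_path).parent
    checks = []
    for out in record.outputs:
        path = base / out["path"] if isinstance(out, Mapping) else base / out.path
        want = out["md5"] if isinstance(out, Mapping) else out.md5
        if not path.exists():
            checks.append(FileCheck(path, False, "missing"))
        elif compute_md5(path) != want:
            checks.append(FileCheck(path, False, "checksum-mismatch"))
        else:
            checks.append(FileCheck(path, True, "ok"))
    return VerificationReport(tuple(checks))
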