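"""Data recipes: parameterized, reproducible data-curation procedures.

A *data recipe* packages an ad hoc data preprocessing shell script into a
self-contained, reusable unit: a script template with ``{{param}}``
placeholders, a typed parameter list, output extraction patterns (globs) and
the software tools the script relies on. Recipes are serialized one per YAML
file and are the unit that gets compiled to CWL, evaluated into curated data
files, and indexed in the recipe hub.

Placeholder syntax is ``{{name}}`` — deliberately distinct from shell
``$var`` so templates can contain ordinary shell variables untouched.
Bound values are substituted after backslash-escaping the characters that
are unsafe inside a double-quoted shell word (``\\ " ` $``), so arbitrary
text survives a round trip through the shell while simple values appear
verbatim in the rendered script.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from ._yamlio import read_yaml, write_yaml
from .errors import RecipeValidationError, BindingError

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
PLACEHOLDER_RE = re.compile(r"\{\{([A-Za-z_][A-Za-z0-9_]*)\}\}")
VERSION_RE = re.compile(r"^\d+(\.\d+){0,2}([-.+][0-9A-Za-z.-]+)?$")

PARAMETER_TYPES = ("string", "int", "float", "boolean", "file")
OUTPUT_ROLES = ("primary", "secondary")
REQUIREMENT_SOURCES = ("system", "conda-spec", "container-uri")

# characters that can break out of a double-quoted shell word
_SHELL_SPECIAL = '\\"`$'


@dataclass(frozen=True)
class ParameterSpec:
    """A typed recipe input parameter.

    ``ptype`` is one of ``string``, ``int``, ``float``, ``boolean``,
    ``file``; optional parameters (``required=False``) must carry a default
    conforming to that type.
    """

    name: str
    ptype: str = "string"
    required: bool = True
    default: Any = None
    description: str = ""

    def __post_init__(self) -> None:
        if not IDENTIFIER_RE.match(self.name):
            raise RecipeValidationError(f"invalid parameter name: {self.name!r}")
        if self.ptype not in PARAMETER_TYPES:
            raise RecipeValidationError(
                f"parameter {self.name!r}: unknown type {self.ptype!r}"
            )
        if not self.required and self.default is None:
            raise RecipeValidationError(
                f"parameter {self.name!r}: optional parameters need a default"
            )
        if self.default is not None:
            try:
                object.__setattr__(
                    self, "default", coerce_value(self.ptype, self.default)
                )
            except ValueError as exc:
                raise RecipeValidationError(
                    f"parameter {self.name!r}: default does not conform to "
                    f"{self.ptype}: {exc}"
                ) from exc


@dataclass(frozen=True)
class SoftwareRequirement:
    """A software tool the recipe script relies on.

    ``source`` says where the tool comes from: already on the ``system``, a
    ``conda-spec`` (e.g. ``bioconda::samtools=1.17``) or a ``container-uri``.
    """

    tool: str
    version: str = "unversioned"
    source: str = "system"
    spec: str = ""

    def __post_init__(self) -> None:
        if not self.tool:
            raise RecipeValidationError("software requirement needs a tool name")
        if self.source not in REQUIREMENT_SOURCES:
            raise RecipeValidationError(
                f"requirement {self.tool!r}: unknown source {self.source!r}"
            )
        if self.source != "system" and not self.spec:
            raise RecipeValidationError(
                f"requirement {self.tool!r}: source {self.source!r} needs a spec"
            )


@dataclass(frozen=True)
class OutputSpec:
    """An output extraction pattern: files matching ``glob`` (relative to the
    evaluation output directory) are collected under ``name`` with the given
    role (``primary`` data versus ``secondary`` companions such as indexes).
    """

    name: str
    glob: str
    role: str = "primary"

    def __post_init__(self) -> None:
        if not IDENTIFIER_RE.match(self.name):
            raise RecipeValidationError(f"invalid output name: {self.name!r}")
        if not self.glob:
            raise RecipeValidationError(f"output {self.name!r}: empty glob")
        if self.glob.startswith(("/", "~")) or ".." in Path(self.glob).parts:
            raise RecipeValidationError(
                f"output {self.name!r}: glob must be relative: {self.glob!r}"
            )
        if self.role not in OUTPUT_ROLES:
            raise RecipeValidationError(
                f"output {self.name!r}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class Recipe:
    """A validated data recipe.

    Invariants enforced at construction: every ``{{token}}`` in the script
    template names a declared parameter, every declared parameter is used at
    least once, parameter/output names are unique, and at least one output
    has role ``primary``.
    """

    name: str
    version: str
    description: str
    script_template: str
    parameters: tuple[ParameterSpec, ...] = ()
    outputs: tuple[OutputSpec, ...] = ()
    requirements: tuple[SoftwareRequirement, ...] = ()
    origin: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        object.__setattr__(self, "requirements", tuple(self.requirements))
        problems: list[str] = []
        if not IDENTIFIER_RE.match(self.name):
            problems.append(f"invalid recipe name: {self.name!r}")
        if not VERSION_RE.match(self.version):
            problems.append(f"invalid version: {self.version!r}")
        if not self.script_template:
            problems.append("empty script")
        declared = [p.name for p in self.parameters]
        dupes = {n for n in declared if declared.count(n) > 1}
        if dupes:
            problems.append(f"duplicate parameter names: {sorted(dupes)}")
        used = set(PLACEHOLDER_RE.findall(self.script_template))
        undeclared = sorted(used - set(declared))
        unused = sorted(set(declared) - used)
        if undeclared:
            problems.append(f"undeclared placeholders: {undeclared}")
        if unused:
            problems.append(f"unused parameters: {unused}")
        out_names = [o.name for o in self.outputs]
        if len(set(out_names)) != len(out_names):
            problems.append("duplicate output names")
        if not any(o.role == "primary" for o in self.outputs):
            problems.append("at least one output must have role 'primary'")
        if problems:
            raise RecipeValidationError(
                f"recipe {self.name!r}: " + "; ".join(problems)
            )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "description": self.description,
            "origin": self.origin,
            "script": self.script_template,
            "parameters": [
                {
                    "name": p.name,
                    "type": p.ptype,
                    "required": p.required,
                    "default": p.default,
                    "description": p.description,
                }
                for p in self.parameters
            ],
            "outputs": [
                {"name": o.name, "glob": o.glob, "role": o.role}
                for o in self.outputs
            ],
            "requirements": [
                {
                    "tool": r.tool,
                    "version": r.version,
                    "source": r.source,
                    "spec": r.spec,
                }
                for r in self.requirements
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Recipe":
        if not isinstance(data, Mapping):
            raise RecipeValidationError("recipe document must be a mapping")
        for key in ("name", "version", "script"):
            if key not in data or data[key] in (None, ""):
                raise RecipeValidationError(f"missing required field: {key}")
        params = tuple(
            ParameterSpec(
                name=p["name"],
                ptype=p.get("type", "string"),
                required=bool(p.get("required", True)),
                default=p.get("default"),
                description=p.get("description", ""),
            )
            for p in data.get("parameters") or ()
        )
        outputs = tuple(
            OutputSpec(name=o["name"], glob=o["glob"], role=o.get("role", "primary"))
            for o in data.get("outputs") or ()
        )
        reqs = tuple(
            SoftwareRequirement(
                tool=r["tool"],
                version=r.get("version", "unversioned"),
                source=r.get("source", "system"),
                spec=r.get("spec", ""),
            )
            for r in data.get("requirements") or ()
        )
        return cls(
            name=data["name"],
            version=str(data["version"]),
            description=data.get("description", ""),
            script_template=data["script"],
            parameters=params,
            outputs=outputs,
            requirements=reqs,
            origin=data.get("origin"),
        )


Bindings = Mapping[str, Any]


def make_recipe(
    script: str,
    parameters: list[ParameterSpec] | tuple[ParameterSpec, ...] = (),
    outputs: list[OutputSpec] | tuple[OutputSpec, ...] = (),
    requirements: list[SoftwareRequirement] | tuple[SoftwareRequirement, ...] = (),
    *,
    name: str,
    version: str = "1.0.0",
    description: str = "",
    origin: str | None = None,
) -> Recipe:
    """Create a :class:`Recipe` from a shell script and its declarations.

    The placeholder/parameter cross-check happens here (via the Recipe
    invariants): undeclared placeholders, unused parameters and duplicate
    parameter names all raise :class:`RecipeValidationError` naming the
    offending tokens.
    """
    if not script:
        raise RecipeValidationError("empty script")
    return Recipe(
        name=name,
        version=version,
        description=description,
        script_template=script,
        parameters=tuple(parameters),
        outputs=tuple(outputs),
        requirements=tuple(requirements),
        origin=origin,
    )


def coerce_value(ptype: str, value: Any) -> Any:
    """Coerce ``value`` to the Python type for ``ptype``.

    Numeral text is accepted for int/float and ``"true"``/``"false"`` for
    boolean, because CLI bindings arrive as text. Raises ``ValueError`` on
    mismatch.
    """
    if ptype == "string":
        if isinstance(value, str):
            return value
        raise ValueError(f"expected string, got {type(value).__name__}")
    if ptype == "file":
        if isinstance(value, (str, Path)) and str(value):
            return str(value)
        raise ValueError("expected a file path")
    if ptype == "int":
        if isinstance(value, bool):
            raise ValueError("expected int, got boolean")
        if isinstance(value, int):
            return value
        if isinstance(value, str) and re.match(r"^[+-]?\d+$", value.strip()):
            return int(value)
        raise ValueError(f"expected int, got {value!r}")
    if ptype == "float":
        if isinstance(value, bool):
            raise ValueError("expected float, got boolean")
        if isinstance(value, (int, float)):
            return float(value)
        if isinstance(value, str):
            try:
                return float(value)
            except ValueError:
                pass
        raise ValueError(f"expected float, got {value!r}")
    if ptype == "boolean":
        if isinstance(value, bool):
            return value
        if isinstance(value, str) and value.strip().lower() in ("true", "false"):
            return value.strip().lower() == "true"
        raise ValueError(f"expected boolean, got {value!r}")
    raise ValueError(f"unknown parameter type {ptype!r}")


def render_value(ptype: str, value: Any) -> str:
    """Render a coerced value as the text substituted into the script."""
    if ptype == "boolean":
        return "true" if value else "false"
    if ptype == "float":
        return repr(float(value))
    return str(value)


def validate_bindings(recipe: Recipe, bindings: Bindings) -> list[str]:
    """Check bindings against the recipe; return violations (empty = valid).

    Violations are ``missing:<name>``, ``undeclared:<name>`` or
    ``type:<name> expected <ptype>``.
    """
    violations: list[str] = []
    declared = {p.name: p for p in recipe.parameters}
    for key in bindings:
        if key not in declared:
            violations.append(f"undeclared:{key}")
    for p in recipe.parameters:
        if p.name not in bindings:
            if p.required:
                violations.append(f"missing:{p.name}")
            continue
        try:
            coerce_value(p.ptype, bindings[p.name])
        except ValueError:
            violations.append(f"type:{p.name} expected {p.ptype}")
    return violations


def resolve_bindings(recipe: Recipe, bindings: Bindings) -> dict[str, Any]:
    """Validate, coerce and default-fill bindings; raise BindingError if invalid.

    Returns a mapping covering every declared parameter, in declaration
    order, with values coerced to their Python types.
    """
    violations = validate_bindings(recipe, bindings)
    if violations:
        raise BindingError(violations)
    resolved: dict[str, Any] = {}
    for p in recipe.parameters:
        if p.name in bindings:
            resolved[p.name] = coerce_value(p.ptype, bindings[p.name])
        else:
            resolved[p.name] = p.default
    return resolved


def shell_escape(text: str) -> str:
    """Escape text for safe substitution inside a double-quoted shell word."""
    return "".join("\\" + c if c in _SHELL_SPECIAL else c for c in text)


def render_script(recipe: Recipe, bindings: Bindings) -> str:
    """Substitute bound values into the script template.

    Rendering is pure: identical inputs give identical text, and no
    ``{{`` placeholder survives in the output. Values pass through
    :func:`shell_escape` so text containing quotes or ``$`` cannot break
    the surrounding command.
    """
    resolved = resolve_bindings(recipe, bindings)
    ptypes = {p.name: p.ptype for p in recipe.parameters}

    def _sub(match: re.Match) -> str:
        name = match.group(1)
        return shell_escape(render_value(ptypes[name], resolved[name]))

    return PLACEHOLDER_RE.sub(_sub, recipe.script_template)


def write_recipe(recipe: Recipe, path: str | Path) -> Path:
    """Serialize a recipe to its YAML file (conventionally ``<name>.yaml``)."""
    return write_yaml(recipe.to_dict(), path)


def read_recipe(path: str | Path) -> Recipe:
    """Parse and validate a recipe YAML file; inverse of :func:`write_recipe`."""
    return Recipe.from_dict(read_yaml(path))
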