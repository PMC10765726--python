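"""Compile recipes to CWL v1.2 CommandLineTool documents.

The recipe's multi-tool shell script is carried whole into CWL: the script
template is embedded via ``InitialWorkDirRequirement`` and executed with
``sh``. Parameters are documented as typed CWL inputs but bound by template
substitution when a job is prepared, not by CWL command-line bindings —
this preserves the "one script drives multiple tools" model instead of
splitting the recipe into per-tool steps. Software requirements become
``SoftwareRequirement`` *hints* (environment provisioning is the
evaluator's job, not the CWL engine's).

Serialization is deterministic: fixed key order (cwlVersion, class, doc,
requirements, hints, inputs, outputs, baseCommand) and stable YAML style,
so repeated writes are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from ._yamlio import dump_yaml, read_yaml
from .errors import RecipeParseError
from .recipe import Recipe

SCRIPT_ENTRYNAME = "script.sh"

# recipe parameter type -> CWL type
CWL_TYPE_MAP = {
    "string": "string",
    "int": "int",
    "float": "float",
    "boolean": "boolean",
    "file": "File",
}
_CWL_TO_PTYPE = {v: k for k, v in CWL_TYPE_MAP.items()}


@dataclass(frozen=True)
class CwlInput:
    id: str
    cwl_type: str
    default: Any = None
    doc: str = ""


@dataclass(frozen=True)
class CwlOutput:
    id: str
    cwl_type: str  # "File" for primaries, "File[]" for secondaries
    glob: str


@dataclass(frozen=True)
class CwlDocument:
    """Structured CWL v1.2 CommandLineTool equivalent of a recipe."""

    doc: str
    script: str
    inputs: tuple[CwlInput, ...]
    outputs: tuple[CwlOutput, ...]
    hints: tuple[Mapping, ...] = ()
    cwl_version: str = "v1.2"
    tool_class: str = "CommandLineTool"
    base_command: tuple[str, ...] = ("sh", SCRIPT_ENTRYNAME)

    def to_mapping(self) -> dict:
        """The document as a plain mapping in canonical key order."""
        inputs: dict[str, Any] = {}
        for inp in self.inputs:
            entry: dict[str, Any] = {"type": inp.cwl_type}
            if inp.default is not None:
                entry["default"] = inp.default
            if inp.doc:
                entry["doc"] = inp.doc
            inputs[inp.id] = entry
        outputs = {
            out.id: {
                "type": out.cwl_type,
                "outputBinding": {"glob": out.glob},
            }
            for out in self.outputs
        }
        mapping: dict[str, Any] = {
            "cwlVersion": self.cwl_version,
            "class": self.tool_class,
            "doc": self.doc,
            "requirements": [
                {
                    "class": "InitialWorkDirRequirement",
                    "listing": [
                        {"entryname": SCRIPT_ENTRYNAME, "entry": self.script}
                    ],
                }
            ],
        }
        if self.hints:
            mapping["hints"] = [dict(h) for h in self.hints]
        mapping["inputs"] = inputs
        mapping["outputs"] = outputs
        mapping["baseCommand"] = list(self.base_command)
        return mapping

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CwlDocument":
        try:
            listing = data["requirements"][0]["listing"][0]
            inputs = tuple(
                CwlInput(
                    id=iid,
                    cwl_type=spec["type"],
                    default=spec.get("default"),
                    doc=spec.get("doc", ""),
                )
                for iid, spec in (data.get("inputs") or {}).items()
            )
            outputs = tuple(
                CwlOutput(
                    id=oid,
                    cwl_type=spec["type"],
                    glob=spec["outputBinding"]["glob"],
                )
                for oid, spec in (data.get("outputs") or {}).items()
            )
            return cls(
                doc=data.get("doc", ""),
                script=listing["entry"],
                inputs=inputs,
                outputs=outputs,
                hints=tuple(data.get("hints") or ()),
                cwl_version=data["cwlVersion"],
                tool_class=data["class"],
                base_command=tuple(data["baseCommand"]),
            )
        except (KeyError, IndexError, TypeError) as exc:
            raise RecipeParseError(f"not a recipekit CWL document: {exc!r}") from exc


def to_cwl(recipe: Recipe) -> CwlDocument:
    """Map a recipe to its CWL CommandLineTool form.

    The mapping is total and deterministic: every parameter becomes a typed
    input (string/int/float/boolean/File), every output pattern becomes a
    glob-bound output — ``File`` for the primary data file, ``File[]`` for
    secondary companions whose globs may legitimately match several files.
    """
    inputs = tuple(
        CwlInput(
            id=p.name,
            cwl_type=CWL_TYPE_MAP[p.ptype],
            default=p.default,
            doc=p.description,
        )
        for p in recipe.parameters
    )
    outputs = tuple(
        CwlOutput(
            id=o.name,
            cwl_type="File" if o.role == "primary" else "File[]",
            glob=o.glob,
        )
        for o in recipe.outputs
    )
    hints: tuple[Mapping, ...] = ()
    if recipe.requirements:
        packages = []
        for req in recipe.requirements:
            pkg: dict[str, Any] = {"package": req.tool}
            if req.version != "unversioned":
                pkg["version"] = [req.version]
            if req.spec:
                pkg["specs"] = [req.spec]
            packages.append(pkg)
        hints = ({"class": "SoftwareRequirement", "packages": packages},)
    return CwlDocument(
        doc=recipe.description,
        script=recipe.script_template,
        inputs=inputs,
        outputs=outputs,
        hints=hints,
    )


def write_cwl(doc: CwlDocument, path: str | Path) -> Path:
    """Write the document as YAML; repeated writes are byte-identical."""
    path = Path(path)
    path.write_text(dump_yaml(doc.to_mapping()))
    return path


def read_cwl(path: str | Path) -> CwlDocument:
    return CwlDocument.from_mapping(read_yaml(path))
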