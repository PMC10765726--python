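"""Independent structural validator for CWL v1.2 CommandLineTool documents.

Deliberately written against the CWL v1.2 specification, not against
recipekit's renderer: it loads the emitted YAML with plain ``yaml.safe_load``
and walks the raw mapping. It shares no code with ``recipekit.cwl`` so it
can serve as an oracle for the rendered documents.
"""

from __future__ import annotations

import yaml

CWL_PRIMITIVE_TYPES = {
    "null",
    "boolean",
    "int",
    "long",
    "float",
    "double",
    "string",
    "File",
    "Directory",
}

_KNOWN_REQUIREMENTS = {
    "InlineJavascriptRequirement",
    "SchemaDefRequirement",
    "LoadListingRequirement",
    "DockerRequirement",
    "SoftwareRequirement",
    "InitialWorkDirRequirement",
    "EnvVarRequirement",
    "ShellCommandRequirement",
    "ResourceRequirement",
    "WorkReuse",
    "NetworkAccess",
    "InplaceUpdateRequirement",
    "ToolTimeLimit",
}


def _check_type(t, errors: list[str], where: str) -> None:
    if isinstance(t, str):
        base = t
        while base.endswith("?") or base.endswith("[]"):
            base = base[:-1] if base.endswith("?") else base[:-2]
        if base not in CWL_PRIMITIVE_TYPES:
            errors.append(f"{where}: unknown type {t!r}")
    elif isinstance(t, dict):
        if t.get("type") == "array":
            _check_type(t.get("items"), errors, where)
        elif t.get("type") not in ("enum", "record"):
            errors.append(f"{where}: unknown complex type {t!r}")
    elif isinstance(t, list):
        for item in t:
            _check_type(item, errors, where)
    else:
        errors.append(f"{where}: malformed type {t!r}")


def _iter_params(block, errors: list[str], where: str):
    """CWL allows map or list form for inputs/outputs; yield (id, body)."""
    if isinstance(block, dict):
        for pid, body in block.items():
            yield pid, body if isinstance(body, dict) else {"type": body}
    elif isinstance(block, list):
        for body in block:
            if not isinstance(body, dict) or "id" not in body:
                errors.append(f"{where}: list entry missing id: {body!r}")
                continue
            yield body["id"], body
    elif block is not None:
        errors.append(f"{where}: must be a map or list")


def validate_commandlinetool(text: str) -> list[str]:
    """Return a list of violations; empty means the document is accepted."""
    errors: list[str] = []
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return [f"unparseable YAML: {exc}"]
    if not isinstance(doc, dict):
        return ["document is not a mapping"]

    if doc.get("cwlVersion") != "v1.2":
        errors.append(f"cwlVersion must be v1.2, got {doc.get('cwlVersion')!r}")
    if doc.get("class") != "CommandLineTool":
        errors.append(f"class must be CommandLineTool, got {doc.get('class')!r}")
    if "inputs" not in doc or "outputs" not in doc:
        errors.append("inputs and outputs sections are mandatory")
    if not (
        doc.get("baseCommand")
        or doc.get("arguments")
        or doc.get("requirements")
    ):
        errors.append("no baseCommand, arguments or requirements")

    for iid, body in _iter_params(doc.get("inputs"), errors, "inputs"):
        _check_type(body.get("type"), errors, f"inputs.{iid}")
    n_out = 0
    for oid, body in _iter_params(doc.get("outputs"), errors, "outputs"):
        n_out += 1
        _check_type(body.get("type"), errors, f"outputs.{oid}")
        binding = body.get("outputBinding")
        type_text = str(body.get("type"))
        if "File" in type_text or "Directory" in type_text:
            if not isinstance(binding, dict) or not binding.get("glob"):
                errors.append(f"outputs.{oid}: File output needs outputBinding.glob")
            else:
                glob = binding["glob"]
                if not isinstance(glob, (str, list)):
                    errors.append(f"outputs.{oid}: glob must be string or list")

    for section in ("requirements", "hints"):
        reqs = doc.get(section)
        if reqs is None:
            continue
        if isinstance(reqs, dict):
            items = [dict(body or {}, **{"class": cls}) for cls, body in reqs.items()]
        elif isinstance(reqs, list):
            items = reqs
        else:
            errors.append(f"{section}: must be a map or list")
            continue
        for req in items:
            if not isinstance(req, dict) or "class" not in req:
                errors.append(f"{section}: entry missing class: {req!r}")
                continue
            cls = req["class"]
            if section == "requirements" and cls not in _KNOWN_REQUIREMENTS:
                errors.append(f"requirements: unknown class {cls!r}")
            if cls == "InitialWorkDirRequirement":
                listing = req.get("listing")
                if not isinstance(listing, list) or not listing:
                    errors.append("InitialWorkDirRequirement needs a listing")
                else:
                    for item in listing:
                        if isinstance(item, dict) and "entry" in item:
                            if not item.get("entryname"):
                                errors.append(
                                    "InitialWorkDirRequirement Dirent needs entryname"
                                )
                        elif not isinstance(item, (str, dict)):
                            errors.append(f"bad listing item: {item!r}")
            if cls == "SoftwareRequirement":
                packages = req.get("packages")
                if not isinstance(packages, list) or not packages:
                    errors.append("SoftwareRequirement needs packages")
                else:
                    for pkg in packages:
                        if not isinstance(pkg, dict) or "package" not in pkg:
                            errors.append(f"bad software package: {pkg!r}")

    base = doc.get("baseCommand")
    if base is not None and not (
        isinstance(base, str)
        or (isinstance(base, list) and all(isinstance(x, str) for x in base))
    ):
        errors.append(f"baseCommand must be string or string list: {base!r}")
    return errors
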