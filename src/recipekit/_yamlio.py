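"""Deterministic YAML serialization.

Recipe files, provenance sidecars and CWL documents must serialize stably:
repeated writes of equal data are byte-identical, key order is the order the
caller built, and multi-line shell scripts come out as literal blocks so the
files stay human-readable and diffable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .errors import RecipeParseError


class _StableDumper(yaml.SafeDumper):
    pass


def _represent_str(dumper: yaml.Dumper, data: str):
    if "\n" in data:
        return dumper.represent_scalar("tag:yaml.org,2002:str", data, style="|")
    return dumper.represent_scalar("tag:yaml.org,2002:str", data)


_StableDumper.add_representer(str, _represent_str)


def dump_yaml(obj: Any) -> str:
    return yaml.dump(
        obj,
        Dumper=_StableDumper,
        sort_keys=False,
        default_flow_style=False,
        allow_unicode=True,
        width=10**6,
    )


def load_yaml(text: str, source: str = "<string>") -> Any:
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:  # attach line context when available
        mark = getattr(exc, "problem_mark", None)
        where = f"{source}:{mark.line + 1}:{mark.column + 1}" if mark else source
        raise RecipeParseError(f"malformed YAML at {where}: {exc}") from exc


def write_yaml(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(dump_yaml(obj))
    return path


def read_yaml(path: str | Path) -> Any:
    path = Path(path)
    return load_yaml(path.read_text(), source=str(path))
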