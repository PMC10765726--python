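"""Exception hierarchy for recipekit.

All library errors derive from :class:`RecipeKitError` so callers (and the
CLI) can catch one base class. Validation-style errors carry structured
detail where the contract requires it (e.g. ``BindingError.violations``).
"""

from __future__ import annotations


class RecipeKitError(Exception):
    """Base class for all recipekit errors."""


class RecipeValidationError(RecipeKitError):
    """A recipe (or one of its components) violates a structural invariant."""


class RecipeParseError(RecipeKitError):
    """A recipe/sidecar/CWL document could not be parsed at all."""


class BindingError(RecipeKitError):
    """Parameter bindings are invalid for the target recipe.

    ``violations`` holds the individual rule breaches, each of the form
    ``missing:<name>``, ``undeclared:<name>`` or ``type:<name> expected <ptype>``.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid bindings: " + "; ".join(self.violations))


class EvaluationError(RecipeKitError):
    """The recipe script exited non-zero."""

    def __init__(self, exit_code: int, stderr: str):
        self.exit_code = exit_code
        self.stderr = stderr
        super().__init__(f"script failed with exit code {exit_code}: {stderr.strip()}")


class OutputCollectionError(RecipeKitError):
    """A primary output glob matched no files after a successful run."""

    def __init__(self, glob: str):
        self.glob = glob
        super().__init__(f"primary output glob matched no files: {glob!r}")


class CollisionError(RecipeKitError):
    """Target sidecar prefix already exists with different parameters."""


class IntegrityError(RecipeKitError):
    """A checksum did not match its recorded value."""


class NotFoundError(RecipeKitError):
    """A lookup (record id, bucket entry, ...) found no match."""


class SyncError(RecipeKitError):
    """A recipe source could not be synchronized."""


class ManifestError(RecipeKitError):
    """A bucket manifest is malformed or violates its invariants."""


class ExportError(RecipeKitError):
    """A workflow-input export could not be built."""
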