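"""Exception hierarchy shared by every module."""

from __future__ import annotations


class MicroFhirError(Exception):
    """Base class for all package errors."""


class SnapshotParseError(MicroFhirError):
    """A terminology snapshot file is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class StructuralError(MicroFhirError):
    """A snapshot violates a structural invariant (e.g. an is-a cycle)."""


class UnknownConceptError(MicroFhirError):
    """A code was referenced that the active snapshot does not declare."""


class ConfigurationError(MicroFhirError):
    """A required snapshot / value set / file is not available."""


class ConstructionError(MicroFhirError):
    """A domain object could not be built; names the field and the rule."""

    def __init__(self, field: str, rule_id: str, message: str):
        self.field = field
        self.rule_id = rule_id
        super().__init__(f"{field}: [{rule_id}] {message}")


class InvariantViolation(MicroFhirError):
    """An operation would break a domain invariant."""


class DispatchError(MicroFhirError):
    """A FHIR body could not be mapped to any known profile."""


class IntegrityError(MicroFhirError):
    """A reference inside a report/bundle does not resolve."""


class CannotEncodeError(MicroFhirError):
    """A result has no FHIR representation (e.g. MRGN category 'none')."""
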