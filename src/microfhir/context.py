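"""Active terminology context (snapshot registry + value-set catalog).

Domain-object invariants such as "the organism is a member of the organism
value set" need terminology to be answerable at construction time.  The
active context defaults to the bundled fixture snapshots and catalog; real
terminology releases are plugged in by swapping it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .terminology import Catalog, SnapshotRegistry, ValueSetDef, default_catalog, default_registry


@dataclass
class TerminologyContext:
    registry: SnapshotRegistry
    catalog: Catalog

    def valueset(self, name_or_url: str) -> ValueSetDef:
        return self.catalog.resolve(name_or_url)


_ACTIVE: Optional[TerminologyContext] = None


def active_context() -> TerminologyContext:
    global _ACTIVE
    if _ACTIVE is None:
        _ACTIVE = TerminologyContext(registry=default_registry(), catalog=default_catalog())
    return _ACTIVE


def set_active_context(
    registry: Optional[SnapshotRegistry] = None, catalog: Optional[Catalog] = None
) -> TerminologyContext:
    """Replace the active context (None restores the bundled default)."""
    global _ACTIVE
    if registry is None and catalog is None:
        _ACTIVE = None
        return active_context()
    _ACTIVE = TerminologyContext(
        registry=registry if registry is not None else default_registry(),
        catalog=catalog if catalog is not None else default_catalog(),
    )
    return _ACTIVE
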