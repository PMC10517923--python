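"""Terminology engine: snapshots, value sets, expansion and membership.

Two snapshot dialects exist.  *Hierarchical* snapshots (SNOMED CT-like) carry
an acyclic is-a graph and answer descendant queries; *tabular* snapshots
(LOINC-like) carry a per-code attribute map over the multi-axial parts
Property, Method, Class and Component.

Value sets are either *extensional* (an enumerated member list) or
*intensional* (a rule evaluated against a snapshot).  The supported rule
language is exactly what the profiles need:

* hierarchical — a union of include roots, each either strict descendants
  (``<``) or descendant-or-self (``<<``), minus the descendant-or-self
  subtrees of the exclude roots;
* tabular — a conjunction of part constraints (``equals`` / ``not-equals`` /
  ``in``), matched case-insensitively.

Full ECL is deliberately out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import networkx as nx
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import systems
from .errors import (
    ConfigurationError,
    SnapshotParseError,
    StructuralError,
    UnknownConceptError,
)

__all__ = [
    "ConceptRef",
    "CodeSystemSnapshot",
    "IncludeRoot",
    "PartConstraint",
    "IntensionalRule",
    "ValueSetDef",
    "SnapshotRegistry",
    "load_snapshot",
    "descendants",
    "ancestors",
    "expand",
    "contains",
    "load_catalog",
    "default_registry",
    "default_catalog",
    "get_valueset",
]

PART_NAMES = ("property", "method", "class", "component")

HIERARCHICAL_COLUMNS = ["code", "display", "parent_codes"]
TABULAR_COLUMNS = ["code", "display", "property", "method", "class", "component"]


class ConceptRef(BaseModel):
    """A (system, code, display) triple — the atom of every binding.

    Identity (equality / hashing) is on system and code only; the display is
    carried for humans and never compared.
    """

    model_config = ConfigDict(frozen=True)

    system: str
    code: str
    display: Optional[str] = None

    @field_validator("system")
    @classmethod
    def _system_registered(cls, v: str) -> str:
        if not systems.is_registered(v):
            raise ValueError(f"unregistered code system URI: {v!r}")
        return v

    @field_validator("code")
    @classmethod
    def _code_shape(cls, v: str) -> str:
        if not v or any(ch.isspace() for ch in v):
            raise ValueError("code must be non-empty and contain no whitespace")
        return v

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ConceptRef):
            return self.key == other.key
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.system}|{self.code}"


@dataclass
class CodeSystemSnapshot:
    """In-memory terminology snapshot, hierarchical or tabular.

    ``graph`` holds parent→child edges for hierarchical systems; ``parts``
    holds the per-code attribute map for tabular ones.  Exactly one of the
    two is populated.
    """

    system: str
    version: str = "fixture"
    displays: dict[str, str] = field(default_factory=dict)
    graph: Optional[nx.DiGraph] = None
    parts: Optional[dict[str, dict[str, str]]] = None

    def __post_init__(self) -> None:
        if (self.graph is None) == (self.parts is None):
            raise StructuralError(
                "snapshot must be either hierarchical (graph) or tabular (parts)"
            )
        if self.graph is not None:
            for parent, child in self.graph.edges:
                for endpoint in (parent, child):
                    if endpoint not in self.displays:
                        raise StructuralError(
                            f"edge endpoint {endpoint!r} is not a declared concept"
                        )
            if not nx.is_directed_acyclic_graph(self.graph):
                cycle = nx.find_cycle(self.graph)
                raise StructuralError(
                    f"is-a graph contains a cycle through concept {cycle[0][0]!r}"
                )
        else:
            assert self.parts is not None
            for code in self.parts:
                if code not in self.displays:
                    raise StructuralError(f"parts row for undeclared concept {code!r}")

    @property
    def dialect(self) -> str:
        return "hierarchical" if self.graph is not None else "tabular"

    @property
    def codes(self) -> set[str]:
        return set(self.displays)

    def __contains__(self, code: str) -> bool:
        return code in self.displays

    def ref(self, code: str) -> ConceptRef:
        """ConceptRef for a declared code, carrying the snapshot display."""
        if code not in self.displays:
            raise UnknownConceptError(f"{code!r} not in snapshot {self.system}")
        return ConceptRef(system=self.system, code=code, display=self.displays[code])

    def require(self, code: str) -> str:
        if code not in self.displays:
            raise UnknownConceptError(f"{code!r} not in snapshot {self.system}")
        return code


def load_snapshot(
    path: Union[str, Path],
    dialect: Literal["hierarchical", "tabular"],
    system: Optional[str] = None,
    version: str = "fixture",
) -> CodeSystemSnapshot:
    """Load a tab-separated snapshot file.

    Hierarchical columns: ``code, display, parent_codes`` (``|``-separated
    parents, empty for roots).  Tabular columns: ``code, display, property,
    method, class, component``.  The first line must be the header.  The
    optional ``#system=<uri>`` comment line (or the *system* argument)
    declares the code-system URI; the fixture URI is registered on load.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"snapshot file not found: {path}")
    expected = HIERARCHICAL_COLUMNS if dialect == "hierarchical" else TABULAR_COLUMNS

    displays: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    deferred_parents: dict[str, list[str]] = {}
    parts: dict[str, dict[str, str]] = {}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: Optional[list[str]] = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                text = row[0][1:].strip()
                if text.startswith("system="):
                    system = text[len("system=") :]
                elif text.startswith("version="):
                    version = text[len("version=") :]
                continue
            if header is None:
                header = [c.strip().lower() for c in row]
                if header != expected:
                    raise SnapshotParseError(
                        f"expected columns {expected}, got {header}", line=lineno
                    )
                continue
            if len(row) != len(expected):
                raise SnapshotParseError(
                    f"expected {len(expected)} columns, got {len(row)}", line=lineno
                )
            code = row[0].strip()
            display = row[1].strip()
            if not code or any(ch.isspace() for ch in code):
                raise SnapshotParseError(f"bad code {code!r}", line=lineno)
            if code in displays:
                raise SnapshotParseError(f"duplicate code {code!r}", line=lineno)
            displays[code] = display
            if dialect == "hierarchical":
                parents = [p.strip() for p in row[2].split("|") if p.strip()]
                deferred_parents[code] = parents
            else:
                parts[code] = {
                    name: row[i + 2].strip() for i, name in enumerate(PART_NAMES)
                }
    if header is None:
        raise SnapshotParseError("empty snapshot file", line=0)
    if system is None:
        raise ConfigurationError(f"no code-system URI declared for {path}")
    systems.register_system(system)

    if dialect == "hierarchical":
        for child, parents in deferred_parents.items():
            for parent in parents:
                if parent not in displays:
                    raise SnapshotParseError(
                        f"parent {parent!r} of {child!r} is not declared", line=0
                    )
                edges.append((parent, child))
        graph = nx.DiGraph()
        graph.add_nodes_from(displays)
        graph.add_edges_from(edges)
        return CodeSystemSnapshot(
            system=system, version=version, displays=displays, graph=graph
        )
    return CodeSystemSnapshot(
        system=system, version=version, displays=displays, parts=parts
    )


def descendants(
    snapshot: CodeSystemSnapshot, root: str, include_self: bool = False
) -> set[str]:
    """Transitive closure of child edges below *root* (plus *root* if asked)."""
    if snapshot.graph is None:
        raise StructuralError("descendants() requires a hierarchical snapshot")
    snapshot.require(root)
    out = set(nx.descendants(snapshot.graph, root))
    if include_self:
        out.add(root)
    return out


def ancestors(snapshot: CodeSystemSnapshot, code: str) -> set[str]:
    """All transitive parents of *code* (excluding itself)."""
    if snapshot.graph is None:
        raise StructuralError("ancestors() requires a hierarchical snapshot")
    snapshot.require(code)
    return set(nx.ancestors(snapshot.graph, code))


# ---------------------------------------------------------------------------
# Value sets
# ---------------------------------------------------------------------------


class IncludeRoot(BaseModel):
    """One include clause: ``<code`` (strict) or ``<<code`` (or-self)."""

    model_config = ConfigDict(frozen=True)

    code: str
    include_self: bool = False


class PartConstraint(BaseModel):
    """One conjunct of a tabular rule, matched case-insensitively."""

    model_config = ConfigDict(frozen=True)

    part: Literal["property", "method", "class", "component"]
    op: Literal["equals", "not-equals", "in"]
    value: Union[str, tuple[str, ...]]

    @model_validator(mode="after")
    def _value_shape(self) -> "PartConstraint":
        if self.op == "in" and isinstance(self.value, str):
            raise ValueError("'in' constraint needs a list of values")
        if self.op != "in" and not isinstance(self.value, str):
            raise ValueError(f"{self.op!r} constraint needs a single string value")
        return self

    def matches(self, row: dict[str, str]) -> bool:
        actual = row.get(self.part, "").lower()
        if self.op == "equals":
            return actual == str(self.value).lower()
        if self.op == "not-equals":
            return actual != str(self.value).lower()
        return actual in {str(v).lower() for v in self.value}


class IntensionalRule(BaseModel):
    """Rule of an intensional value set, for one code system."""

    model_config = ConfigDict(frozen=True)

    system: str
    include_roots: tuple[IncludeRoot, ...] = ()
    exclude_roots: tuple[str, ...] = ()
    part_constraints: tuple[PartConstraint, ...] = ()

    @model_validator(mode="after")
    def _exactly_one_family(self) -> "IntensionalRule":
        hierarchical = bool(self.include_roots)
        tabular = bool(self.part_constraints)
        if hierarchical == tabular:
            raise ValueError(
                "rule must have include_roots (hierarchical) XOR part_constraints (tabular)"
            )
        if tabular and self.exclude_roots:
            raise ValueError("exclude_roots only apply to hierarchical rules")
        return self


class ValueSetDef(BaseModel):
    """A value set: extensional member list or intensional rule."""

    model_config = ConfigDict(frozen=True)

    url: str
    name: Optional[str] = None
    kind: Literal["extensional", "intensional"]
    members: Optional[tuple[ConceptRef, ...]] = None
    rule: Optional[IntensionalRule] = None

    @model_validator(mode="after")
    def _kind_payload(self) -> "ValueSetDef":
        if self.kind == "extensional" and (self.members is None or self.rule is not None):
            raise ValueError("extensional value set must have members and no rule")
        if self.kind == "intensional" and (self.rule is None or self.members is not None):
            raise ValueError("intensional value set must have a rule and no members")
        return self

    @property
    def member_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(m.key for m in self.members or ())


class SnapshotRegistry:
    """Mapping of code-system URI → snapshot."""

    def __init__(self, snapshots: Iterable[CodeSystemSnapshot] = ()):
        self._by_system: dict[str, CodeSystemSnapshot] = {}
        for snap in snapshots:
            self.add(snap)

    def add(self, snapshot: CodeSystemSnapshot) -> None:
        self._by_system[snapshot.system] = snapshot

    def get(self, system: str) -> CodeSystemSnapshot:
        try:
            return self._by_system[system]
        except KeyError:
            raise ConfigurationError(f"no snapshot loaded for system {system!r}") from None

    def __contains__(self, system: str) -> bool:
        return system in self._by_system

    def systems(self) -> list[str]:
        return sorted(self._by_system)


def expand(valueset: ValueSetDef, snapshots: SnapshotRegistry) -> set[ConceptRef]:
    """Materialize a value set as a duplicate-free set of ConceptRefs."""
    if valueset.kind == "extensional":
        return set(valueset.members or ())
    rule = valueset.rule
    assert rule is not None
    snap = snapshots.get(rule.system)
    if rule.include_roots:
        included: set[str] = set()
        for root in rule.include_roots:
            included |= descendants(snap, root.code, include_self=root.include_self)
        for excl in rule.exclude_roots:
            included -= descendants(snap, excl, include_self=True)
        return {snap.ref(code) for code in included}
    assert snap.parts is not None
    out = set()
    for code, row in snap.parts.items():
        if all(c.matches(row) for c in rule.part_constraints):
            out.add(snap.ref(code))
    return out


def contains(
    valueset: ValueSetDef, concept: ConceptRef, snapshots: SnapshotRegistry
) -> bool:
    """Membership test, without materializing the expansion.

    For intensional sets an unknown code raises :class:`UnknownConceptError`
    rather than returning False, to surface snapshot/fixture mismatches.
    """
    if valueset.kind == "extensional":
        return concept.key in valueset.member_keys
    rule = valueset.rule
    assert rule is not None
    if concept.system != rule.system:
        return False
    snap = snapshots.get(rule.system)
    if rule.include_roots:
        snap.require(concept.code)
        lineage = ancestors(snap, concept.code) | {concept.code}
        for excl in rule.exclude_roots:
            if excl in lineage:
                return False
        for root in rule.include_roots:
            if root.code in lineage and (root.include_self or root.code != concept.code):
                return True
        return False
    assert snap.parts is not None
    row = snap.parts.get(concept.code)
    if row is None:
        raise UnknownConceptError(f"{concept.code!r} not in snapshot {snap.system}")
    return all(c.matches(row) for c in rule.part_constraints)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


def _parse_valueset(doc: dict) -> ValueSetDef:
    kind = doc.get("kind")
    if kind == "extensional":
        members = tuple(
            ConceptRef(
                system=m.get("system", doc.get("system")),
                code=str(m["code"]),
                display=m.get("display"),
            )
            for m in doc.get("members", [])
        )
        return ValueSetDef(
            url=doc["url"], name=doc.get("name"), kind="extensional", members=members
        )
    include = tuple(
        IncludeRoot(code=str(r["code"]), include_self=bool(r.get("include_self", False)))
        for r in doc.get("include", [])
    )
    exclude = tuple(str(c) for c in doc.get("exclude", []))
    parts = tuple(
        PartConstraint(
            part=c["part"],
            op=c["op"],
            value=tuple(c["value"]) if isinstance(c["value"], list) else c["value"],
        )
        for c in doc.get("parts", [])
    )
    rule = IntensionalRule(
        system=doc["system"],
        include_roots=include,
        exclude_roots=exclude,
        part_constraints=parts,
    )
    return ValueSetDef(url=doc["url"], name=doc.get("name"), kind="intensional", rule=rule)


class Catalog(dict):
    """Value-set catalog keyed by canonical URL, with name aliases."""

    def __init__(self, definitions: Iterable[ValueSetDef]):
        super().__init__()
        self.by_name: dict[str, ValueSetDef] = {}
        for vs in definitions:
            self[vs.url] = vs
            if vs.name:
                if vs.name in self.by_name:
                    raise ConfigurationError(f"duplicate value-set name {vs.name!r}")
                self.by_name[vs.name] = vs

    def resolve(self, name_or_url: str) -> ValueSetDef:
        if name_or_url in self:
            return self[name_or_url]
        if name_or_url in self.by_name:
            return self.by_name[name_or_url]
        raise ConfigurationError(f"unknown value set {name_or_url!r}")


def load_catalog(path: Union[str, Path]) -> Catalog:
    """Load a YAML value-set catalog (a list of value-set documents)."""
    with Path(path).open(encoding="utf-8") as fh:
        docs = yaml.safe_load(fh)
    if not isinstance(docs, list):
        raise ConfigurationError("catalog must be a YAML list of value sets")
    return Catalog(_parse_valueset(d) for d in docs)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("microfhir").joinpath("data", name)))


_DEFAULT_REGISTRY: Optional[SnapshotRegistry] = None
_DEFAULT_CATALOG: Optional[Catalog] = None


def default_registry() -> SnapshotRegistry:
    """Registry over the bundled fixture snapshots (cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = SnapshotRegistry(
            [
                load_snapshot(_data_path("snomed_mini.tsv"), "hierarchical"),
                load_snapshot(_data_path("loinc_mini.tsv"), "tabular"),
            ]
        )
    return _DEFAULT_REGISTRY


def default_catalog() -> Catalog:
    """The bundled value-set catalog (cached)."""
    global _DEFAULT_CATALOG
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = load_catalog(_data_path("valuesets.yaml"))
    return _DEFAULT_CATALOG


def get_valueset(name_or_url: str) -> ValueSetDef:
    return default_catalog().resolve(name_or_url)


def registry_from_dir(directory: Union[str, Path]) -> SnapshotRegistry:
    """Load ``snomed_mini.tsv`` / ``loinc_mini.tsv`` from a directory."""
    directory = Path(directory)
    return SnapshotRegistry(
        [
            load_snapshot(directory / "snomed_mini.tsv", "hierarchical"),
            load_snapshot(directory / "loinc_mini.tsv", "tabular"),
        ]
    )
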