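"""Typed domain objects for the ten microbiology observation kinds.

The information model groups laboratory examinations into three main
diagnostic blocks — culture (with microscopy), molecular diagnostics and
immunology/serology — plus a *further properties* group for everything that
characterizes an already-detected organism (multidrug-resistance type, MRGN
class, resistance mechanisms, virulence factors).

Two result styles exist and must not be mixed:

* detection-style kinds (culture, microscopy, virulence factor) answer with
  detected / not detected / inconclusive;
* positivity-style kinds (molecular, serology, resistance mechanism) answer
  with positive / weakly positive / negative / inconclusive.

Every observation carries the fixed category code 18725-2 "Microbiology
studies (set)".  Patient/encounter/specimen are opaque reference strings;
those resources live in other modules of the wider data set.

Validator error messages are prefixed with a stable rule id (the same ids
the profile validator reports), so :func:`new_observation` can surface the
violated rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Literal, Optional, Union

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from . import codes, systems
from .context import active_context
from .errors import ConstructionError, InvariantViolation
from .terminology import ConceptRef, contains

__all__ = [
    "Quantity",
    "DetectionResult",
    "PositivityResult",
    "OrganismRef",
    "Score",
    "AssayComponent",
    "Avidity",
    "GeneName",
    "CultureDetection",
    "ColonyCount",
    "SusceptibilityTest",
    "Microscopy",
    "MolecularDetection",
    "SerologyImmunology",
    "MDROType",
    "MRGNClassification",
    "ResistanceMechanism",
    "VirulenceFactor",
    "MicrobiologyReport",
    "MicrobiologyObservation",
    "KindInfo",
    "OBSERVATION_KINDS",
    "BLOCKS",
    "new_observation",
    "link_culture_children",
]

BLOCKS = ("culture", "molecular", "serology", "further_properties")

CATEGORY = codes.CATEGORY_MICRO


def _rule_error(rule_id: str, message: str) -> ValueError:
    return ValueError(f"{rule_id}: {message}")


class Quantity(BaseModel):
    """A numeric result with a UCUM unit from the registered subset."""

    model_config = ConfigDict(frozen=True)

    value: float
    unit: str

    @field_validator("unit")
    @classmethod
    def _unit_registered(cls, v: str) -> str:
        if v not in systems.UCUM_UNITS:
            raise _rule_error("quantity-unit-ucum", f"unit {v!r} not in the UCUM subset")
        return v


def _coerce_result(v: Any) -> Any:
    if isinstance(v, ConceptRef):
        return {"value": v}
    if isinstance(v, str):
        return {"value": {"system": systems.SNOMED, "code": v}}
    return v


class DetectionResult(BaseModel):
    """Qualitative detected / not detected / inconclusive result."""

    model_config = ConfigDict(frozen=True)

    value: ConceptRef

    _coerce = model_validator(mode="before")(classmethod(lambda cls, v: _coerce_result(v)))

    @field_validator("value")
    @classmethod
    def _in_detection_vs(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.DETECTION_RESULTS:
            raise _rule_error(
                "result-vs-mismatch",
                f"{v.code} is not in the detected/not-detected/inconclusive value set",
            )
        return v

    @classmethod
    def detected(cls) -> "DetectionResult":
        return cls(value=codes.DETECTED)

    @classmethod
    def not_detected(cls) -> "DetectionResult":
        return cls(value=codes.NOT_DETECTED)

    @property
    def is_detected(self) -> bool:
        return self.value == codes.DETECTED


class PositivityResult(BaseModel):
    """Qualitative positive / weakly positive / negative / inconclusive result."""

    model_config = ConfigDict(frozen=True)

    value: ConceptRef

    _coerce = model_validator(mode="before")(classmethod(lambda cls, v: _coerce_result(v)))

    @field_validator("value")
    @classmethod
    def _in_positivity_vs(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.POSITIVITY_RESULTS:
            raise _rule_error(
                "result-vs-mismatch",
                f"{v.code} is not in the positive/weakly-positive/negative/inconclusive value set",
            )
        return v

    @classmethod
    def positive(cls) -> "PositivityResult":
        return cls(value=codes.POSITIVE)

    @classmethod
    def negative(cls) -> "PositivityResult":
        return cls(value=codes.NEGATIVE)


class OrganismRef(BaseModel):
    """An organism concept, checked against the organism value set

    (the organism hierarchy minus the excluded kingdom subtrees)."""

    model_config = ConfigDict(frozen=True)

    concept: ConceptRef

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, v: Any) -> Any:
        if isinstance(v, ConceptRef):
            return {"concept": v}
        if isinstance(v, str):
            return {"concept": {"system": systems.SNOMED, "code": v}}
        return v

    @field_validator("concept")
    @classmethod
    def _in_organism_vs(cls, v: ConceptRef) -> ConceptRef:
        ctx = active_context()
        if not contains(ctx.valueset("organism"), v, ctx.registry):
            raise _rule_error(
                "organism-vs-membership", f"{v.code} is not in the organism value set"
            )
        return v


class Score(BaseModel):
    """Sputum-quality (Bartlett) or bacterial-vaginosis (Nugent) score."""

    model_config = ConfigDict(frozen=True)

    score_code: ConceptRef
    score_value: int

    @field_validator("score_code")
    @classmethod
    def _allowed(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.SCORE_CODES:
            raise _rule_error("score-code-allowed", f"{v.code} is not a registered score code")
        return v


class AssayComponent(BaseModel):
    """Numeric sub-result of a molecular assay (cycle threshold, viral load)."""

    model_config = ConfigDict(frozen=True)

    component_code: ConceptRef
    value: Quantity

    @field_validator("component_code")
    @classmethod
    def _allowed(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.ASSAY_COMPONENT_CODES:
            raise _rule_error(
                "molecular-assay-code",
                f"{v.code} is not the nucleic-acid-assay or PCR procedure code",
            )
        return v


class Avidity(BaseModel):
    """Antibody avidity: qualitative high/low or a numeric result."""

    model_config = ConfigDict(frozen=True)

    value: Union[Quantity, ConceptRef]

    @field_validator("value")
    @classmethod
    def _qualitative_allowed(cls, v: Union[Quantity, ConceptRef]) -> Union[Quantity, ConceptRef]:
        if isinstance(v, ConceptRef) and v not in (codes.AVIDITY_HIGH, codes.AVIDITY_LOW):
            raise _rule_error(
                "avidity-value-vs", f"{v.code} is not the high or low qualifier"
            )
        return v

    @property
    def code(self) -> ConceptRef:
        return codes.AVIDITY_CODE


class GeneName(BaseModel):
    """Gene/mutation named via a genomics database when no LOINC code exists."""

    model_config = ConfigDict(frozen=True)

    name: str
    source: Literal["NCBI", "EMBL-EBI"]
    identifier: str


# ---------------------------------------------------------------------------
# Observation kinds
# ---------------------------------------------------------------------------


class MicrobiologyObservation(BaseModel):
    """Base of the ten observation kinds.  ``kind`` is a class attribute."""

    model_config = ConfigDict(frozen=True)

    kind: str = "abstract"
    id: str

    @field_validator("id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v:
            raise _rule_error("id-required", "observation id must be non-empty")
        return v

    @property
    def category(self) -> ConceptRef:
        return CATEGORY


class CultureDetection(MicrobiologyObservation):
    """Microorganism detection via culture (code 11475-1)."""

    kind: Literal["culture"] = "culture"
    specimen_ref: Optional[str] = None
    result: DetectionResult
    organisms: tuple[OrganismRef, ...] = ()
    children: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _organism_requires_detected(self) -> "CultureDetection":
        if self.organisms and not self.result.is_detected:
            raise _rule_error(
                "organism-requires-detected",
                "an organism may only be reported when the culture result is detected",
            )
        return self

    @model_validator(mode="after")
    def _children_unique(self) -> "CultureDetection":
        if len(set(self.children)) != len(self.children):
            raise _rule_error("children-unique", "duplicate child observation ids")
        return self


class ColonyCount(MicrobiologyObservation):
    """Colony count: numeric *or* semi-quantitative, never both."""

    kind: Literal["colony_count"] = "colony_count"
    code: ConceptRef
    quantity: Optional[Quantity] = None
    semiquantitative: Optional[ConceptRef] = None

    @field_validator("code")
    @classmethod
    def _code_in_vs(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.COLONY_COUNT_CODES:
            raise _rule_error("colony-code-vs", f"{v.code} is not a colony-count code")
        return v

    @field_validator("semiquantitative")
    @classmethod
    def _semiquant_in_vs(cls, v: Optional[ConceptRef]) -> Optional[ConceptRef]:
        if v is not None and v not in codes.SEMIQUANT_RESULTS:
            raise _rule_error(
                "result-vs-mismatch", f"{v.code} is not a semi-quantitative result code"
            )
        return v

    @model_validator(mode="after")
    def _choice(self) -> "ColonyCount":
        if (self.quantity is None) == (self.semiquantitative is None):
            raise _rule_error(
                "colony-choice-exclusive",
                "exactly one of quantity / semiquantitative must be given",
            )
        if self.quantity is not None:
            allowed = codes.COLONY_COUNT_UNITS[self.code.code]
            if self.quantity.unit not in allowed:
                raise _rule_error(
                    "colony-unit-class",
                    f"unit {self.quantity.unit!r} does not fit code {self.code.code} "
                    f"(allowed: {sorted(allowed)})",
                )
        return self


class SusceptibilityTest(MicrobiologyObservation):
    """Phenotypic antimicrobial susceptibility test for one agent.

    The qualitative category follows either the EUCAST three-value system
    (S / I / R, with I meaning susceptible-increased exposure in current
    versions) or the CLSI-style five-value system (S / SDD / I / R / NS).
    Because both committees have redefined categories over the years, the
    standard's version is mandatory whenever a category is reported.
    """

    kind: Literal["susceptibility"] = "susceptibility"
    agent_test: ConceptRef
    mic: Optional[Quantity] = None
    interpretation: Optional[str] = None
    scheme: Literal["EUCAST", "CLSI"] = "EUCAST"
    scheme_version: str = ""
    method: Optional[ConceptRef] = None

    @field_validator("agent_test")
    @classmethod
    def _agent_in_vs(cls, v: ConceptRef) -> ConceptRef:
        ctx = active_context()
        if not contains(ctx.valueset("susceptibility-tests"), v, ctx.registry):
            raise _rule_error(
                "susc-code-vs",
                f"{v.code} is not in the phenotypic susceptibility-test value set",
            )
        return v

    @field_validator("mic")
    @classmethod
    def _mic_unit(cls, v: Optional[Quantity]) -> Optional[Quantity]:
        if v is not None and v.unit not in systems.MIC_UNITS:
            raise _rule_error(
                "mic-unit-allowed", f"unit {v.unit!r} is not a MIC/MLC unit"
            )
        return v

    @model_validator(mode="after")
    def _interpretation_rules(self) -> "SusceptibilityTest":
        if self.interpretation is not None:
            allowed = (
                codes.EUCAST_CATEGORIES if self.scheme == "EUCAST" else codes.CLSI_CATEGORIES
            )
            if self.interpretation not in allowed:
                raise _rule_error(
                    "susc-interpretation-vs",
                    f"{self.interpretation!r} is not a {self.scheme} category",
                )
            if not self.scheme_version:
                raise _rule_error(
                    "susc-version-required",
                    "the standard's version is mandatory when a category is reported",
                )
        return self

    @property
    def interpretation_system(self) -> str:
        return systems.EUCAST if self.scheme == "EUCAST" else systems.HL7_INTERPRETATION


class Microscopy(MicrobiologyObservation):
    """Microscopic examination (code 117259009) with its method and sub-results."""

    kind: Literal["microscopy"] = "microscopy"
    result: DetectionResult
    method: ConceptRef
    organisms: tuple[OrganismRef, ...] = ()
    morphology_note: Optional[str] = None
    score: Optional[Score] = None
    quantity: Optional[Quantity] = None
    semiquantitative: Optional[ConceptRef] = None

    @field_validator("method")
    @classmethod
    def _method_in_vs(cls, v: ConceptRef) -> ConceptRef:
        ctx = active_context()
        enumerated = ctx.valueset("microscopy-methods")
        staining = ctx.valueset("staining-methods")
        if not (
            contains(enumerated, v, ctx.registry) or contains(staining, v, ctx.registry)
        ):
            raise _rule_error(
                "microscopy-method-vs",
                f"{v.code} is neither an enumerated microscopy method nor a staining method",
            )
        return v

    @field_validator("semiquantitative")
    @classmethod
    def _semiquant_in_vs(cls, v: Optional[ConceptRef]) -> Optional[ConceptRef]:
        if v is not None and v not in codes.SEMIQUANT_RESULTS:
            raise _rule_error(
                "result-vs-mismatch", f"{v.code} is not a semi-quantitative result code"
            )
        return v

    @model_validator(mode="after")
    def _quantity_choice(self) -> "Microscopy":
        if self.quantity is not None and self.semiquantitative is not None:
            raise _rule_error(
                "colony-choice-exclusive",
                "quantity and semiquantitative are alternatives, not both",
            )
        return self


class MolecularDetection(MicrobiologyObservation):
    """Detection of genetic material (code 92253-4)."""

    kind: Literal["molecular"] = "molecular"
    result: PositivityResult
    organisms: tuple[OrganismRef, ...] = ()
    assay_components: tuple[AssayComponent, ...] = ()


class SerologyImmunology(MicrobiologyObservation):
    """Antibody/antigen examination: generic procedure code or specific LOINC."""

    kind: Literal["serology"] = "serology"
    test: ConceptRef = codes.IMMUNOLOGY_CODE
    result: PositivityResult
    antigen_quantity: Optional[Quantity] = None
    antibody_quantity: Optional[Quantity] = None
    avidity: Optional[Avidity] = None

    @field_validator("test")
    @classmethod
    def _test_allowed(cls, v: ConceptRef) -> ConceptRef:
        if v == codes.IMMUNOLOGY_CODE:
            return v
        ctx = active_context()
        if v.system == systems.LOINC and contains(
            ctx.valueset("serology"), v, ctx.registry
        ):
            return v
        raise _rule_error(
            "serology-code-vs",
            f"{v.code} is neither the generic immunology procedure nor a serology LOINC code",
        )


class MDROType(MicrobiologyObservation):
    """Type of antimicrobial resistant organism (code 1285113001)."""

    kind: Literal["mdro_type"] = "mdro_type"
    value: ConceptRef

    @field_validator("value")
    @classmethod
    def _value_in_vs(cls, v: ConceptRef) -> ConceptRef:
        ctx = active_context()
        if not contains(ctx.valueset("mdro-type"), v, ctx.registry):
            raise _rule_error(
                "mdro-value-vs",
                f"{v.code} is not under a resistant-organism hierarchy",
            )
        return v


class MRGNClassification(MicrobiologyObservation):
    """KRINKO MRGN class (code 99780-9, answers 2/3/4MRGN)."""

    kind: Literal["mrgn_class"] = "mrgn_class"
    value: ConceptRef

    @field_validator("value")
    @classmethod
    def _value_in_vs(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.MRGN_ANSWERS.values():
            raise _rule_error("mrgn-value-vs", f"{v.code} is not an MRGN answer code")
        return v


class ResistanceMechanism(MicrobiologyObservation):
    """Presence of a resistance gene or mutation."""

    kind: Literal["resistance_mechanism"] = "resistance_mechanism"
    test: ConceptRef
    result: PositivityResult
    gene_name: Optional[GeneName] = None

    @field_validator("test")
    @classmethod
    def _test_in_vs(cls, v: ConceptRef) -> ConceptRef:
        if v in codes.GENERIC_RESISTANCE_CODES:
            return v
        ctx = active_context()
        if contains(ctx.valueset("resistance-genes"), v, ctx.registry):
            return v
        raise _rule_error(
            "resistance-code-vs",
            f"{v.code} is neither a resistance-gene/mutation code nor a generic code",
        )

    @model_validator(mode="after")
    def _gene_required_for_generic(self) -> "ResistanceMechanism":
        if self.test in codes.GENERIC_RESISTANCE_CODES and self.gene_name is None:
            raise _rule_error(
                "gene-component-required",
                "generic gene/mutation codes require the gene name component",
            )
        return self


class VirulenceFactor(MicrobiologyObservation):
    """Presence of a virulence factor (toxins, proteins); detection-style result."""

    kind: Literal["virulence_factor"] = "virulence_factor"
    test: ConceptRef
    result: DetectionResult

    @field_validator("test")
    @classmethod
    def _test_in_vs(cls, v: ConceptRef) -> ConceptRef:
        ctx = active_context()
        if not contains(ctx.valueset("virulence"), v, ctx.registry):
            raise _rule_error(
                "virulence-code-vs", f"{v.code} is not in the virulence-factor value set"
            )
        return v


class MicrobiologyReport(BaseModel):
    """Diagnostic report grouping observations under a study type."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["report"] = "report"
    id: str
    category: ConceptRef
    results: tuple[str, ...] = ()
    conclusion: Optional[str] = None

    @field_validator("category")
    @classmethod
    def _category_in_vs(cls, v: ConceptRef) -> ConceptRef:
        if v not in codes.STUDY_TYPES.values():
            raise _rule_error(
                "report-study-type-vs", f"{v.code} is not a microbiology study-type code"
            )
        return v


# ---------------------------------------------------------------------------
# Registry & operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KindInfo:
    kind: str
    block: str
    cls: type
    result_style: str  # detection | positivity | none


OBSERVATION_KINDS: dict[str, KindInfo] = {
    info.kind: info
    for info in (
        KindInfo("culture", "culture", CultureDetection, "detection"),
        KindInfo("colony_count", "culture", ColonyCount, "none"),
        KindInfo("susceptibility", "culture", SusceptibilityTest, "none"),
        KindInfo("microscopy", "culture", Microscopy, "detection"),
        KindInfo("molecular", "molecular", MolecularDetection, "positivity"),
        KindInfo("serology", "serology", SerologyImmunology, "positivity"),
        KindInfo("mdro_type", "further_properties", MDROType, "none"),
        KindInfo("mrgn_class", "further_properties", MRGNClassification, "none"),
        KindInfo("resistance_mechanism", "further_properties", ResistanceMechanism, "positivity"),
        KindInfo("virulence_factor", "further_properties", VirulenceFactor, "detection"),
    )
}


def _construction_error(exc: ValidationError) -> ConstructionError:
    first = exc.errors()[0]
    field = ".".join(str(p) for p in first["loc"]) or "<payload>"
    msg = first["msg"]
    prefix = "Value error, "
    if msg.startswith(prefix):
        msg = msg[len(prefix) :]
    rule_id, sep, rest = msg.partition(": ")
    if not sep or " " in rule_id:
        rule_id, rest = "invalid-payload", msg
    return ConstructionError(field=field, rule_id=rule_id, message=rest)


def new_observation(kind: str, payload: dict[str, Any]) -> MicrobiologyObservation:
    """Construct a validated observation of the given kind from a field map."""
    if kind not in OBSERVATION_KINDS:
        raise ConstructionError("kind", "unknown-kind", f"unknown observation kind {kind!r}")
    cls = OBSERVATION_KINDS[kind].cls
    try:
        return cls(**payload)
    except ValidationError as exc:
        raise _construction_error(exc) from exc


def link_culture_children(
    culture: CultureDetection, children: list[str]
) -> CultureDetection:
    """Append child observation ids (colony counts, susceptibility tests)
    to a detected culture; duplicate-free, order preserved."""
    if not culture.result.is_detected:
        raise InvariantViolation(
            "characterizing observations can only be linked to a detected culture"
        )
    merged = list(culture.children)
    for child in children:
        if child not in merged:
            merged.append(child)
    return culture.model_copy(update={"children": tuple(merged)})
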