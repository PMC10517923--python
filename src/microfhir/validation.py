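"""Profile validator: terminology-driven conformance rules over FHIR bodies.

This is not a general FHIR validator — no StructureDefinition engine, no
FHIRPath.  The rules are hand-compiled from the profiled bindings: fixed
codes, value-set memberships (answered by the terminology engine against
the active snapshots), choice-type exclusivity, the mandatory
standard's-version rule for susceptibility categories, the UCUM unit
whitelist, hasMember target kinds and the gene-component rule for generic
resistance codes.

Severity policy: every profile-derived constraint is an error; unknown
extra elements are warnings only (FHIR resources are open).  Missing
optional elements are never issues — the profiles deliberately fix few
mandatory elements.  Problems are returned as issues, never raised; the
only raising case is unparseable JSON upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Optional, Union

from pydantic import BaseModel, ConfigDict

from . import codes, systems
from .context import active_context
from .errors import DispatchError, UnknownConceptError
from .fhir_io import (
    ROLE_GENE,
    ROLE_ORGANISM,
    ResourceEnvelope,
    dispatch_kind,
)
from .terminology import Catalog, ConceptRef, SnapshotRegistry, contains

__all__ = ["ValidationIssue", "validate", "rule_catalog", "issues_to_operation_outcome"]


class ValidationIssue(BaseModel):
    """One conformance finding: severity, stable rule id, element path."""

    model_config = ConfigDict(frozen=True)

    severity: str  # error | warning
    rule_id: str
    path: str
    message: str

    def sort_key(self) -> tuple[str, str]:
        return (self.path, self.rule_id)


@dataclass(frozen=True)
class RuleSpec:
    rule_id: str
    source: str
    description: str


_RULES: tuple[RuleSpec, ...] = (
    RuleSpec("profile-unrecognized", "shared profile core",
             "The resource matches no known profile or fixed examination code."),
    RuleSpec("category-micro-fixed", "shared profile core",
             "Observation.category must carry the fixed microbiology-studies coding 18725-2."),
    RuleSpec("choice-type-exclusive", "shared profile core",
             "value[x] is a choice: valueQuantity and valueCodeableConcept never coexist."),
    RuleSpec("ucum-unit", "shared profile core",
             "Quantities must use the UCUM system and a unit from the registered subset."),
    RuleSpec("unknown-element", "shared profile core",
             "Element not used by any profile (warning; resources are open)."),
    RuleSpec("culture-code-fixed", "culture-detection profile",
             "Observation.code is fixed to 11475-1 (culture detection)."),
    RuleSpec("result-vs-mismatch", "per-kind result binding",
             "Observation.value coding must come from the kind's result value set."),
    RuleSpec("organism-vs-membership", "organism component binding",
             "Organism components must come from the organism hierarchy minus exclusions."),
    RuleSpec("organism-requires-detected", "culture-detection profile",
             "An organism component is only meaningful when the culture result is detected."),
    RuleSpec("hasmember-target-kind", "culture-detection profile",
             "Culture hasMember links must target colony-count or susceptibility observations."),
    RuleSpec("colony-code-vs", "colony-count profile",
             "Observation.code must be one of the four colony-count codes."),
    RuleSpec("colony-unit-class", "colony-count profile",
             "The quantity unit must fit the chosen colony-count code's unit class."),
    RuleSpec("susc-code-vs", "susceptibility profile",
             "Observation.code must be a phenotypic (non-genotyping) susceptibility test."),
    RuleSpec("susc-interpretation-scheme", "susceptibility profile",
             "Interpretation codings must declare the EUCAST or HL7 category system."),
    RuleSpec("susc-interpretation-vs", "susceptibility profile",
             "Interpretation code must belong to the declared scheme's category set."),
    RuleSpec("susc-version-required", "susceptibility profile",
             "The standard's version is mandatory whenever a category is reported."),
    RuleSpec("microscopy-code-fixed", "microscopy profile",
             "Observation.code is fixed to 117259009 (microscopy)."),
    RuleSpec("microscopy-method-vs", "microscopy profile",
             "Method must be an enumerated microscopy procedure or a staining method."),
    RuleSpec("score-code-allowed", "microscopy profile",
             "Integer score components are restricted to the Bartlett and vaginosis codes."),
    RuleSpec("molecular-code-fixed", "molecular-detection profile",
             "Observation.code is fixed to 92253-4 (molecular detection)."),
    RuleSpec("molecular-assay-code", "molecular-detection profile",
             "Numeric components must use the nucleic-acid-assay or PCR procedure code."),
    RuleSpec("serology-code-vs", "serology-immunology profile",
             "Code must be the generic immunology procedure or a serology LOINC code."),
    RuleSpec("avidity-value-vs", "serology-immunology profile",
             "Qualitative avidity values are restricted to high / low."),
    RuleSpec("mdro-code-fixed", "mdro-type profile",
             "Observation.code is fixed to 1285113001 (resistant-organism type)."),
    RuleSpec("mrgn-code-fixed", "mrgn-classification profile",
             "Observation.code is fixed to 99780-9 (MRGN classification)."),
    RuleSpec("resistance-code-vs", "resistance-mechanism profile",
             "Code must be a resistance-gene/mutation code or a generic gene code."),
    RuleSpec("gene-component-required", "resistance-mechanism profile",
             "Generic gene/mutation codes require the gene-name component."),
    RuleSpec("virulence-code-vs", "virulence-factor profile",
             "Code must come from the virulence-factor value set."),
    RuleSpec("report-category-snomed", "diagnostic-report profile",
             "Report category must carry the fixed microbiology-report coding 4341000179107."),
    RuleSpec("report-study-type-vs", "diagnostic-report profile",
             "Report study type must be one of the five microbiology study codes."),
)

_RULE_IDS = {r.rule_id for r in _RULES}


def rule_catalog() -> list[tuple[str, str, str]]:
    """Stable enumeration of every rule the validator can report."""
    return [(r.rule_id, r.source, r.description) for r in _RULES]


_KNOWN_OBSERVATION_KEYS = {
    "resourceType", "id", "meta", "identifier", "status", "category", "code",
    "subject", "encounter", "specimen", "effectiveDateTime", "issued",
    "performer", "valueQuantity", "valueCodeableConcept", "valueString",
    "valueInteger", "interpretation", "note", "method", "hasMember",
    "component", "basedOn", "derivedFrom", "device", "referenceRange",
}
_KNOWN_REPORT_KEYS = {
    "resourceType", "id", "meta", "identifier", "status", "category", "code",
    "subject", "encounter", "specimen", "result", "conclusion", "issued",
    "effectiveDateTime", "performer", "presentedForm",
}

_RESULT_VS_BY_KIND = {
    "culture": "detection-result",
    "microscopy": "detection-result",
    "virulence_factor": "detection-result",
    "molecular": "positivity-result",
    "serology": "positivity-result",
    "resistance_mechanism": "positivity-result",
    "colony_count": "semiquantitative-result",
    "mdro_type": "mdro-type",
    "mrgn_class": "mrgn-class",
}

_FIXED_CODE_RULES = {
    "culture": ("culture-code-fixed", codes.CULTURE_CODE),
    "microscopy": ("microscopy-code-fixed", codes.MICROSCOPY_CODE),
    "molecular": ("molecular-code-fixed", codes.MOLECULAR_CODE),
    "mdro_type": ("mdro-code-fixed", codes.MDRO_TYPE_CODE),
    "mrgn_class": ("mrgn-code-fixed", codes.MRGN_CODE),
}

_ORGANISM_KINDS = {"culture", "microscopy", "molecular"}


def _codings(cc: Optional[dict[str, Any]]) -> list[dict[str, Any]]:
    return (cc or {}).get("coding", [])


def _first_ref(cc: Optional[dict[str, Any]]) -> Optional[ConceptRef]:
    for coding in _codings(cc):
        if "system" in coding and "code" in coding:
            try:
                return ConceptRef(system=coding["system"], code=coding["code"])
            except ValueError:
                return None
    return None


def _has_coding(cc_list: list[dict[str, Any]], ref: ConceptRef) -> bool:
    return any(
        c.get("system") == ref.system and c.get("code") == ref.code
        for cc in cc_list
        for c in _codings(cc)
    )


def validate(
    envelope: Union[ResourceEnvelope, dict[str, Any]],
    registry: Optional[SnapshotRegistry] = None,
    catalog: Optional[Catalog] = None,
    siblings: Optional[dict[str, dict[str, Any]]] = None,
) -> list[ValidationIssue]:
    """Check a FHIR body against the profiled bindings; return sorted issues.

    ``siblings`` (id → body) enables the hasMember target-kind rule; without
    it, link targets cannot be resolved and that rule is not applied.
    """
    body = envelope.body if isinstance(envelope, ResourceEnvelope) else envelope
    ctx = active_context()
    registry = registry if registry is not None else ctx.registry
    catalog = catalog if catalog is not None else ctx.catalog

    issues: list[ValidationIssue] = []

    def err(rule_id: str, path: str, message: str, severity: str = "error") -> None:
        assert rule_id in _RULE_IDS, rule_id
        issues.append(
            ValidationIssue(severity=severity, rule_id=rule_id, path=path, message=message)
        )

    def in_vs(name: str, ref: ConceptRef) -> bool:
        try:
            return contains(catalog.resolve(name), ref, registry)
        except UnknownConceptError:
            return False

    try:
        kind = dispatch_kind(body)
    except DispatchError as exc:
        return [
            ValidationIssue(
                severity="error", rule_id="profile-unrecognized", path="/", message=str(exc)
            )
        ]

    if kind == "report":
        _validate_report(body, err, in_vs)
        return sorted(issues, key=ValidationIssue.sort_key)

    # (a) fixed category
    if not _has_coding(body.get("category", []), codes.CATEGORY_MICRO):
        err("category-micro-fixed", "/category",
            "category must include LOINC 18725-2 Microbiology studies (set)")

    # unknown elements (warnings)
    for key in sorted(set(body) - _KNOWN_OBSERVATION_KEYS):
        err("unknown-element", f"/{key}", f"element {key!r} is not used by any profile",
            severity="warning")

    # (c) choice-type exclusivity, body level
    if "valueQuantity" in body and "valueCodeableConcept" in body:
        err("choice-type-exclusive", "/valueQuantity",
            "valueQuantity and valueCodeableConcept are alternatives")

    # (e) UCUM whitelist on every quantity
    def check_quantity(q: dict[str, Any], path: str) -> None:
        if q.get("system") != systems.UCUM or q.get("code") not in systems.UCUM_UNITS:
            err("ucum-unit", f"{path}/code",
                f"unit {q.get('code')!r} is not in the registered UCUM subset")

    if "valueQuantity" in body:
        check_quantity(body["valueQuantity"], "/valueQuantity")
    for i, comp in enumerate(body.get("component", [])):
        if "valueQuantity" in comp and "valueCodeableConcept" in comp:
            err("choice-type-exclusive", f"/component/{i}",
                "component value is a choice type")
        if "valueQuantity" in comp:
            check_quantity(comp["valueQuantity"], f"/component/{i}/valueQuantity")

    # (a) fixed / enumerated examination code
    code_ref = _first_ref(body.get("code"))
    code_path = "/code/coding/0/code"
    if kind in _FIXED_CODE_RULES:
        rule_id, fixed = _FIXED_CODE_RULES[kind]
        if code_ref != fixed:
            err(rule_id, code_path, f"code must be fixed to {fixed.code}")
    elif kind == "colony_count":
        if code_ref is None or code_ref not in codes.COLONY_COUNT_CODES:
            err("colony-code-vs", code_path, "code must be one of the four colony-count codes")
    elif kind == "susceptibility":
        if code_ref is None or not in_vs("susceptibility-tests", code_ref):
            err("susc-code-vs", code_path,
                "code must be a phenotypic (non-genotyping) susceptibility test")
    elif kind == "serology":
        ok = code_ref == codes.IMMUNOLOGY_CODE or (
            code_ref is not None and in_vs("serology", code_ref)
        )
        if not ok:
            err("serology-code-vs", code_path,
                "code must be the immunology procedure or a serology LOINC code")
    elif kind == "resistance_mechanism":
        ok = code_ref in codes.GENERIC_RESISTANCE_CODES or (
            code_ref is not None and in_vs("resistance-genes", code_ref)
        )
        if not ok:
            err("resistance-code-vs", code_path,
                "code must be a resistance gene/mutation or generic gene code")
    elif kind == "virulence_factor":
        if code_ref is None or not in_vs("virulence", code_ref):
            err("virulence-code-vs", code_path,
                "code must come from the virulence-factor value set")

    # (b) result value set
    value_ref = _first_ref(body.get("valueCodeableConcept"))
    if body.get("valueCodeableConcept") is not None:
        vs_name = _RESULT_VS_BY_KIND[kind]
        if value_ref is None or not in_vs(vs_name, value_ref):
            err("result-vs-mismatch", "/valueCodeableConcept/coding/0/code",
                f"value must come from the {vs_name} value set")

    # (b) organism components
    if kind in _ORGANISM_KINDS:
        organism_paths = []
        for i, comp in enumerate(body.get("component", [])):
            comp_code = _first_ref(comp.get("code"))
            if comp_code == ROLE_ORGANISM:
                organism_paths.append(i)
                org = _first_ref(comp.get("valueCodeableConcept"))
                if org is None or not in_vs("organism", org):
                    err("organism-vs-membership",
                        f"/component/{i}/valueCodeableConcept/coding/0/code",
                        "organism is not in the organism value set")
        if kind == "culture" and organism_paths and value_ref != codes.DETECTED:
            err("organism-requires-detected", f"/component/{organism_paths[0]}",
                "organism reported although the culture result is not detected")

    # kind-specific rules
    if kind == "colony_count" and "valueQuantity" in body and code_ref is not None:
        allowed = codes.COLONY_COUNT_UNITS.get(code_ref.code)
        unit = body["valueQuantity"].get("code")
        if allowed is not None and unit in systems.UCUM_UNITS and unit not in allowed:
            err("colony-unit-class", "/valueQuantity/code",
                f"unit {unit!r} does not fit colony-count code {code_ref.code}")

    if kind == "susceptibility":
        for i, interp in enumerate(body.get("interpretation", [])):
            for j, coding in enumerate(_codings(interp)):
                base = f"/interpretation/{i}/coding/{j}"
                system = coding.get("system")
                if system == systems.EUCAST:
                    allowed = codes.EUCAST_CATEGORIES
                elif system == systems.HL7_INTERPRETATION:
                    allowed = codes.CLSI_CATEGORIES
                else:
                    err("susc-interpretation-scheme", f"{base}/system",
                        "interpretation system must be the EUCAST or HL7 category system")
                    allowed = None
                if allowed is not None and coding.get("code") not in allowed:
                    err("susc-interpretation-vs", f"{base}/code",
                        f"{coding.get('code')!r} is not a category of the declared scheme")
                if not coding.get("version"):
                    err("susc-version-required", f"{base}/version",
                        "the standard's version is mandatory with a reported category")

    if kind == "microscopy":
        if "method" in body:
            method = _first_ref(body["method"])
            ok = method is not None and (
                in_vs("microscopy-methods", method) or in_vs("staining-methods", method)
            )
            if not ok:
                err("microscopy-method-vs", "/method/coding/0/code",
                    "method is neither an enumerated procedure nor a staining method")
        for i, comp in enumerate(body.get("component", [])):
            if "valueInteger" in comp:
                score_code = _first_ref(comp.get("code"))
                if score_code not in codes.SCORE_CODES:
                    err("score-code-allowed", f"/component/{i}/code/coding/0/code",
                        "integer scores are restricted to the Bartlett and vaginosis codes")

    if kind == "molecular":
        for i, comp in enumerate(body.get("component", [])):
            if "valueQuantity" in comp:
                comp_code = _first_ref(comp.get("code"))
                if comp_code not in codes.ASSAY_COMPONENT_CODES:
                    err("molecular-assay-code", f"/component/{i}/code/coding/0/code",
                        "numeric components must use the nucleic-acid-assay or PCR code")

    if kind == "serology":
        for i, comp in enumerate(body.get("component", [])):
            comp_code = _first_ref(comp.get("code"))
            if comp_code == codes.AVIDITY_CODE and "valueCodeableConcept" in comp:
                v = _first_ref(comp["valueCodeableConcept"])
                if v not in (codes.AVIDITY_HIGH, codes.AVIDITY_LOW):
                    err("avidity-value-vs",
                        f"/component/{i}/valueCodeableConcept/coding/0/code",
                        "qualitative avidity must be high or low")

    if kind == "resistance_mechanism" and code_ref in codes.GENERIC_RESISTANCE_CODES:
        has_gene = any(
            _first_ref(c.get("code")) == ROLE_GENE for c in body.get("component", [])
        )
        if not has_gene:
            err("gene-component-required", "/component",
                "generic gene/mutation codes require the gene-name component")

    # (f) hasMember target kinds (needs sibling resources to resolve)
    if kind == "culture" and siblings is not None:
        for i, member in enumerate(body.get("hasMember", [])):
            ref = member.get("reference", "")
            target_id = ref.split("/", 1)[1] if "/" in ref else ref
            target = siblings.get(target_id)
            if target is None:
                err("hasmember-target-kind", f"/hasMember/{i}/reference",
                    f"link target {target_id!r} was not supplied")
                continue
            try:
                target_kind = dispatch_kind(target)
            except DispatchError:
                target_kind = None
            if target_kind not in ("colony_count", "susceptibility"):
                err("hasmember-target-kind", f"/hasMember/{i}/reference",
                    "culture children must be colony-count or susceptibility observations")

    return sorted(issues, key=ValidationIssue.sort_key)


def _validate_report(body: dict[str, Any], err, in_vs) -> None:
    if not _has_coding(body.get("category", []), codes.REPORT_CATEGORY_SNOMED):
        err("report-category-snomed", "/category",
            "report category must include the microbiology-report coding 4341000179107")
    study = None
    for cc in body.get("category", []):
        for coding in _codings(cc):
            if coding.get("system") == systems.LOINC:
                study = coding
    if study is None or not in_vs(
        "report-study-type", ConceptRef(system=systems.LOINC, code=study.get("code", "x"))
    ):
        err("report-study-type-vs", "/category",
            "report category must include one of the five study-type codes")
    for key in sorted(set(body) - _KNOWN_REPORT_KEYS):
        err("unknown-element", f"/{key}", f"element {key!r} is not used by any profile",
            severity="warning")


def issues_to_operation_outcome(issues: list[ValidationIssue]) -> dict[str, Any]:
    """Render issues as a FHIR OperationOutcome-shaped JSON object."""
    return {
        "resourceType": "OperationOutcome",
        "issue": [
            {
                "severity": i.severity,
                "code": "invariant",
                "details": {"text": f"[{i.rule_id}] {i.message}"},
                "expression": [i.path],
            }
            for i in issues
        ],
    }
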