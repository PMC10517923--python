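"""Profile validator: rule catalog, spec'd findings, single-fault detection."""

from __future__ import annotations

import copy

import pytest

from conftest import (
    _BUILDERS,
    make_colony_count,
    make_culture,
    make_microscopy,
    make_molecular,
    make_report,
    make_susceptibility,
)
from microfhir import codes, systems
from microfhir.fhir_io import to_fhir, to_report_bundle
from microfhir.validation import issues_to_operation_outcome, rule_catalog, validate


def _errors(issues):
    return [i for i in issues if i.severity == "error"]


class TestRuleCatalog:
    def test_contains_the_version_rule_with_its_source(self):
        entries = {rule_id: source for rule_id, source, _ in rule_catalog()}
        assert entries["susc-version-required"] == "susceptibility profile"

    def test_ids_are_unique(self):
        ids = [rule_id for rule_id, _, _ in rule_catalog()]
        assert len(ids) == len(set(ids))

    def test_covers_at_least_the_fixed_value_bindings(self):
        # the profiles fix 12 codes/values outright (examination codes,
        # category, score codes, avidity code, assay component codes)
        assert len(rule_catalog()) >= 12


class TestFindings:
    def test_versionless_interpretation_is_an_error(self):
        body = to_fhir(make_susceptibility()).body
        body = copy.deepcopy(body)
        del body["interpretation"][0]["coding"][0]["version"]
        issues = validate(body)
        assert any(i.rule_id == "susc-version-required" for i in _errors(issues))

    def test_culture_with_positivity_result_is_flagged(self):
        body = copy.deepcopy(to_fhir(make_culture(organisms=(), children=())).body)
        body["valueCodeableConcept"]["coding"][0]["code"] = "10828004"
        issues = validate(body)
        assert [i.rule_id for i in _errors(issues)] == ["result-vs-mismatch"]

    def test_conformant_molecular_observation_has_zero_issues(self):
        assert validate(to_fhir(make_molecular())) == []

    def test_conformant_mrgn_observation_has_zero_issues(self):
        assert validate(to_fhir(_BUILDERS["mrgn_class"]())) == []

    def test_validate_is_pure_and_deterministic(self):
        body = copy.deepcopy(to_fhir(make_culture(organisms=(), children=())).body)
        body["valueCodeableConcept"]["coding"][0]["code"] = "10828004"
        body["category"][0]["coding"][0]["code"] = "0000-0"
        first = validate(body)
        second = validate(body)
        assert first == second
        assert [i.sort_key() for i in first] == sorted(i.sort_key() for i in first)

    def test_operation_outcome_shape(self):
        body = copy.deepcopy(to_fhir(make_culture(organisms=(), children=())).body)
        body["valueCodeableConcept"]["coding"][0]["code"] = "10828004"
        outcome = issues_to_operation_outcome(validate(body))
        assert outcome["resourceType"] == "OperationOutcome"
        assert outcome["issue"][0]["severity"] == "error"


# ---------------------------------------------------------------------------
# single-fault mutation harness: one mutator per catalog rule
# ---------------------------------------------------------------------------


def _culture_with_siblings():
    culture = make_culture(children=("colony-1", "susc-1"))
    bodies = {
        "colony-1": to_fhir(make_colony_count(id="colony-1")).body,
        "susc-1": to_fhir(make_susceptibility(id="susc-1")).body,
        "micro-1": to_fhir(make_microscopy(id="micro-1", organisms=())).body,
    }
    return to_fhir(culture).body, bodies


def _report_body():
    return to_report_bundle(make_report(results=()), [])["entry"][0]["resource"]


def _set(cc_path, value):
    def mutate(body):
        node = body
        for key in cc_path[:-1]:
            node = node[key]
        node[cc_path[-1]] = value

    return mutate


def _culture():
    return to_fhir(make_culture(children=())).body


def _mut_profile_unrecognized(body):
    del body["meta"]
    body["code"]["coding"][0]["code"] = "00000-0"
    return "/"


def _mut_unknown_element(body):
    body["frobnicate"] = True
    return "/frobnicate"


def _mut_choice(body):
    body["valueCodeableConcept"] = {
        "coding": [{"system": systems.SNOMED, "code": "260347006"}]
    }
    return "/valueQuantity"


def _mut_bad_unit(body):
    body["valueQuantity"]["code"] = "mL"
    body["valueQuantity"]["unit"] = "mL"
    return "/valueQuantity/code"


def _mut_wrong_unit_class(body):
    body["valueQuantity"]["code"] = "/g"
    body["valueQuantity"]["unit"] = "/g"
    return "/valueQuantity/code"


def _mut_del_version(body):
    del body["interpretation"][0]["coding"][0]["version"]
    return "/interpretation/0/coding/0/version"


def _mut_drop_components(body):
    del body["component"]
    return "/component"


def _mut_report_category(body):
    body["category"][0]["coding"] = [
        c for c in body["category"][0]["coding"] if c["system"] != systems.SNOMED
    ]
    return "/category"


def _mut_report_study(body):
    for coding in body["category"][0]["coding"]:
        if coding["system"] == systems.LOINC:
            coding["code"] = "18725-2"
    return "/category"


def _code_mut(new_code):
    def mutate(body):
        body["code"]["coding"][0]["code"] = new_code
        return "/code/coding/0/code"

    return mutate


def _value_mut(new_code):
    def mutate(body):
        body["valueCodeableConcept"]["coding"][0]["code"] = new_code
        return "/valueCodeableConcept/coding/0/code"

    return mutate


MUTATIONS: list[tuple[str, str, object, str]] = [
    # (rule_id, base kind or "report"/"culture+siblings", mutator, severity)
    ("profile-unrecognized", "culture", _mut_profile_unrecognized, "error"),
    ("category-micro-fixed", "culture",
     lambda b: (_set(["category", 0, "coding", 0, "code"], "12345-6")(b), "/category")[1],
     "error"),
    ("choice-type-exclusive", "colony_count", _mut_choice, "error"),
    ("ucum-unit", "colony_count", _mut_bad_unit, "error"),
    ("unknown-element", "culture", _mut_unknown_element, "warning"),
    ("culture-code-fixed", "culture", _code_mut("92253-4"), "error"),
    ("result-vs-mismatch", "culture", _value_mut("10828004"), "error"),
    ("organism-vs-membership", "culture",
     lambda b: (_set(
         ["component", 0, "valueCodeableConcept", "coding", 0, "code"], "990000102")(b),
         "/component/0/valueCodeableConcept/coding/0/code")[1], "error"),
    ("organism-requires-detected", "culture",
     lambda b: (_set(["valueCodeableConcept", "coding", 0, "code"], "260415000")(b),
                "/component/0")[1], "error"),
    ("hasmember-target-kind", "culture+siblings",
     lambda b: (_set(["hasMember", 0, "reference"], "Observation/micro-1")(b),
                "/hasMember/0/reference")[1], "error"),
    ("colony-code-vs", "colony_count", _code_mut("99780-9"), "error"),
    ("colony-unit-class", "colony_count", _mut_wrong_unit_class, "error"),
    ("susc-code-vs", "susceptibility", _code_mut("99998-9"), "error"),
    ("susc-interpretation-scheme", "susceptibility",
     lambda b: (_set(["interpretation", 0, "coding", 0, "system"], systems.LOINC)(b),
                "/interpretation/0/coding/0/system")[1], "error"),
    ("susc-interpretation-vs", "susceptibility",
     lambda b: (_set(["interpretation", 0, "coding", 0, "code"], "NS")(b),
                "/interpretation/0/coding/0/code")[1], "error"),
    ("susc-version-required", "susceptibility", _mut_del_version, "error"),
    ("microscopy-code-fixed", "microscopy", _code_mut("104157003"), "error"),
    ("microscopy-method-vs", "microscopy",
     lambda b: (_set(["method", "coding", 0, "code"], "9718006")(b),
                "/method/coding/0/code")[1], "error"),
    ("score-code-allowed", "microscopy",
     lambda b: (_set(["component", 1, "code", "coding", 0],
                     {"system": systems.LOINC, "code": "92251-8"})(b),
                "/component/1/code/coding/0/code")[1], "error"),
    ("molecular-code-fixed", "molecular", _code_mut("11475-1"), "error"),
    ("molecular-assay-code", "molecular",
     lambda b: (_set(["component", 1, "code", "coding", 0],
                     {"system": systems.COMPONENT_ROLE, "code": "quantity"})(b),
                "/component/1/code/coding/0/code")[1], "error"),
    ("serology-code-vs", "serology",
     lambda b: (_set(["code", "coding", 0],
                     {"system": systems.LOINC, "code": "99996-3"})(b),
                "/code/coding/0/code")[1], "error"),
    ("avidity-value-vs", "serology",
     lambda b: (_set(["component", 1, "valueCodeableConcept", "coding", 0, "code"],
                     "260373001")(b),
                "/component/1/valueCodeableConcept/coding/0/code")[1], "error"),
    ("mdro-code-fixed", "mdro_type", _code_mut("77559007"), "error"),
    ("mrgn-code-fixed", "mrgn_class", _code_mut("11475-1"), "error"),
    ("resistance-code-vs", "resistance_mechanism", _code_mut("88603-6"), "error"),
    ("gene-component-required", "resistance_mechanism", _mut_drop_components, "error"),
    ("virulence-code-vs", "virulence_factor", _code_mut("18945-6"), "error"),
    ("report-category-snomed", "report", _mut_report_category, "error"),
    ("report-study-type-vs", "report", _mut_report_study, "error"),
]


def _base_for(base_key: str):
    if base_key == "report":
        return _report_body(), None
    if base_key == "culture+siblings":
        return _culture_with_siblings()
    if base_key == "culture":
        return _culture(), None
    return to_fhir(_BUILDERS[base_key]()).body, None


class TestSingleFaultDetection:
    @pytest.mark.parametrize(
        "rule_id,base_key,mutate,severity",
        MUTATIONS,
        ids=[m[0] for m in MUTATIONS],
    )
    def test_mutation_triggers_exactly_the_rule_at_its_path(
        self, rule_id, base_key, mutate, severity
    ):
        base, siblings = _base_for(base_key)
        assert _errors(validate(base, siblings=siblings)) == [], "base must be clean"
        body = copy.deepcopy(base)
        path = mutate(body)
        issues = validate(body, siblings=siblings)
        matching = [i for i in issues if i.rule_id == rule_id and i.path == path]
        assert matching, f"{rule_id} not raised at {path}: {issues}"
        assert all(i.severity == severity for i in matching)

    def test_every_catalog_rule_has_a_mutation(self):
        assert {m[0] for m in MUTATIONS} == {r for r, _, _ in rule_catalog()}
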