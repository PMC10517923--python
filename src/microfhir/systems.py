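"""Canonical code-system URIs and the registered UCUM unit subset.

Every coded value in the package is a :class:`~microfhir.terminology.ConceptRef`
whose ``system`` must be one of the URIs registered here.  Real SNOMED CT and
LOINC releases are never redistributed; the bundled snapshots are small
fixtures wired from the codes the profiles bind.
"""

from __future__ import annotations

SNOMED = "http://snomed.info/sct"
LOINC = "http://loinc.org"
UCUM = "http://unitsofmeasure.org"

#: Self-defined EUCAST susceptibility-category code system (S / I / R).  EUCAST
#: does not publish a FHIR code system; a draft one is shipped as a fixture.
EUCAST = "https://example.org/fhir/microbiology/CodeSystem/eucast-susceptibility-category"

#: HL7 v3 ObservationInterpretation — carries the five-value CLSI-style set
#: (S, SDD, I, R, NS).
HL7_INTERPRETATION = "http://terminology.hl7.org/CodeSystem/v3-ObservationInterpretation"

#: Local component-role codes for Observation.component.code slots the
#: profiles leave uncoded (organism name, free numeric results, gene name).
COMPONENT_ROLE = "https://example.org/fhir/microbiology/CodeSystem/component-role"

#: Gene / mutation identifier sources for resistance-mechanism components.
NCBI_GENE = "https://www.ncbi.nlm.nih.gov/gene"
EMBL_EBI = "https://www.ebi.ac.uk/ena"

#: Placeholder canonical namespace for artefacts with no published URL.
NAMESPACE = "https://example.org/fhir/microbiology/"

_REGISTERED_SYSTEMS: set[str] = {
    SNOMED,
    LOINC,
    UCUM,
    EUCAST,
    HL7_INTERPRETATION,
    COMPONENT_ROLE,
    NCBI_GENE,
    EMBL_EBI,
}


def register_system(uri: str) -> None:
    """Register an additional (fixture) code-system URI."""
    _REGISTERED_SYSTEMS.add(uri)


def is_registered(uri: str) -> bool:
    return uri in _REGISTERED_SYSTEMS or uri.startswith(NAMESPACE)


# ---------------------------------------------------------------------------
# UCUM subset
# ---------------------------------------------------------------------------

#: The UCUM codes the profiles need: MIC/MLC concentrations, arbitrary serologic
#: units, colony-count units (per volume / absolute / per mass / CFU per
#: volume) and dimensionless counts such as PCR cycle thresholds.
#: µg/mL is carried in its case-sensitive ASCII form "ug/mL".
UCUM_UNITS: frozenset[str] = frozenset(
    {
        "ug/mL",
        "mg/L",
        "[arb'U]/mL",
        "[IU]/mL",
        "/mL",
        "/g",
        "1",
        "[CFU]/mL",
    }
)

#: Units acceptable for MIC / MLC numeric susceptibility results.
MIC_UNITS: frozenset[str] = frozenset({"ug/mL", "mg/L", "[arb'U]/mL"})
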