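"""Terminology codes bound by the microbiology profiles.

Codes printed in the published profile tables are carried verbatim.  The
fixture snapshot rows (see :mod:`microfhir.synth`) wire these codes into a
toy hierarchy: everything below the named domain/kingdom roots is explicitly
fictional and must not be mistaken for terminology truth.  Codes that exist
only to give the fixture shape are marked ``[synthetic fixture concept]`` in
their display.
"""

from __future__ import annotations

from . import systems
from .terminology import ConceptRef


def snomed(code: str, display: str | None = None) -> ConceptRef:
    return ConceptRef(system=systems.SNOMED, code=code, display=display)


def loinc(code: str, display: str | None = None) -> ConceptRef:
    return ConceptRef(system=systems.LOINC, code=code, display=display)


# --- category / report -----------------------------------------------------

CATEGORY_MICRO = loinc("18725-2", "Microbiology studies (set)")
REPORT_CATEGORY_SNOMED = snomed("4341000179107", "Microbiology report")

STUDY_TYPES = {
    "bacterial": loinc("92894-5", "Microbiology - bacterial studies"),
    "viral": loinc("92893-7", "Microbiology - viral studies"),
    "mycobacteriology": loinc("96397-5", "Microbiology - mycobacteriology studies"),
    "mycology": loinc("96398-3", "Microbiology - mycology studies"),
    "parasitic": loinc("92892-9", "Microbiology - parasitic studies"),
}

# --- examination codes ------------------------------------------------------

CULTURE_CODE = loinc("11475-1", "Microorganism identified in Specimen by Culture")
MICROSCOPY_CODE = snomed("117259009", "Microscopy (procedure)")
MOLECULAR_CODE = loinc(
    "92253-4", "Microorganism identified in Isolate or Specimen by Molecular genetics method"
)
# carried verbatim as printed (8 digits) — do not "correct"
IMMUNOLOGY_CODE = snomed("25231800", "Immunology laboratory test (procedure)")
MDRO_TYPE_CODE = snomed(
    "1285113001", "Type of antimicrobial resistant organism (observable entity)"
)
MRGN_CODE = loinc("99780-9", "Multidrug resistant Gram-negative organism classification [Type]")

COLONY_COUNT_CODES = (
    loinc("49223-1", "Colony count [#/volume] in Unspecified specimen by Visual count"),
    loinc("564-5", "Colony count [#] in Unspecified specimen by Visual count"),
    loinc("38436-2", "Colony count [#/mass] in Unspecified specimen by Visual count"),
    loinc("20774-6", "Colony count [Units/volume] in Unspecified specimen by Visual count"),
)

#: UCUM unit class per colony-count code (volume / absolute / mass / CFU-volume).
COLONY_COUNT_UNITS = {
    "49223-1": frozenset({"/mL"}),
    "564-5": frozenset({"1"}),
    "38436-2": frozenset({"/g"}),
    "20774-6": frozenset({"[CFU]/mL"}),
}

# --- qualitative results ----------------------------------------------------

DETECTED = snomed("260373001", "Detected (qualifier value)")
NOT_DETECTED = snomed("260415000", "Not detected (qualifier value)")
INCONCLUSIVE = snomed("419984006", "Inconclusive (qualifier value)")
POSITIVE = snomed("10828004", "Positive (qualifier value)")
WEAKLY_POSITIVE = snomed("260408008", "Weakly positive (qualifier value)")
NEGATIVE = snomed("260385009", "Negative (qualifier value)")

DETECTION_RESULTS = (DETECTED, NOT_DETECTED, INCONCLUSIVE)
POSITIVITY_RESULTS = (POSITIVE, WEAKLY_POSITIVE, NEGATIVE, INCONCLUSIVE)

SEMIQUANT_RESULTS = (
    snomed("260347006", "Present + out of ++++ (qualifier value)"),
    snomed("260348001", "Present ++ out of ++++ (qualifier value)"),
    snomed("260349009", "Present +++ out of ++++ (qualifier value)"),
    snomed("260350009", "Present ++++ out of ++++ (qualifier value)"),
)

AVIDITY_CODE = snomed("77559007", "Immunologic avidity, function (observable entity)")
AVIDITY_HIGH = snomed("75540009", "High (qualifier value)")
AVIDITY_LOW = snomed("62482003", "Low (qualifier value)")

# --- organisms --------------------------------------------------------------

ORGANISM_ROOT = "410607006"
#: The five sub-hierarchies removed from the organism value set.
ORGANISM_EXCLUSIONS = (
    "243387004",  # Domain Archaea
    "387961004",  # Kingdom Animalia
    "414261007",  # Kingdom Plantae
    "770557006",  # Kingdom Viridiplantae
    "414061000",  # Slime mold
)

GRAM_NEGATIVE_ROOT = "87172008"  # Gram-negative bacterium grouping (fixture wiring)
P_AERUGINOSA = "52499004"
E_COLI = "112283007"
K_PNEUMONIAE = "56415008"
A_BAUMANNII = "91288006"

RESISTANT_BACTERIA_ROOT = "409793007"
RESISTANT_VIRUS_ROOT = "409795000"
RESISTANT_FUNGI_ROOT = "409794001"
CARBAPENEM_RESISTANT = "707497007"
CARBAPENEM_RESISTANT_PA = "726492000"

# --- microscopy methods -----------------------------------------------------

MICROSCOPY_METHODS = (
    snomed("58586006", "Microbial ova-parasite examination (procedure)"),
    snomed("117023006", "Thick film peripheral blood smear (procedure)"),
    snomed("408195004", "Thick film for malarial parasites (procedure)"),
    snomed("117024000", "Thin film peripheral blood smear method (procedure)"),
    snomed("67047002", "Microbial wet smear (procedure)"),
    snomed("27318003", "Potassium hydroxide preparation (procedure)"),
    snomed("104157003", "Light microscopy (procedure)"),
    snomed("73512001", "Electron microscopic study (procedure)"),
)
STAINING_ROOT = "127790008"  # Staining method (procedure)

SCORE_CODES = (
    loinc("75371-5", "Bartlett score of Sputum Qualitative by Light microscopy"),
    loinc("43391-2", "Bacterial vaginosis score"),
)

# --- molecular / resistance / virulence ------------------------------------

NUCLEIC_ACID_ASSAY = snomed("398545005", "Nucleic acid assay (procedure)")
PCR = snomed("9718006", "Polymerase chain reaction analysis (procedure)")
ASSAY_COMPONENT_CODES = (NUCLEIC_ACID_ASSAY, PCR)

GENERIC_GENE_DETECTED = loinc(
    "92251-8", "Microorganism gene detected [Presence] by Molecular method"
)
GENERIC_MUTATION_DETECTED = loinc(
    "92246-8", "Microorganism resistance mutation detected [Presence] by Molecular method"
)
GENERIC_RESISTANCE_CODES = (GENERIC_GENE_DETECTED, GENERIC_MUTATION_DETECTED)

VANB_GENE = loinc("72421-1", "Vancomycin resistance vanB gene [Presence] by Molecular method")

METHICILLIN_SUSC = loinc("18945-6", "Methicillin [Susceptibility]")

# --- interpretation ---------------------------------------------------------

EUCAST_CATEGORIES = ("S", "I", "R")
CLSI_CATEGORIES = ("S", "SDD", "I", "R", "NS")

EUCAST_DISPLAYS = {
    "S": "Susceptible",
    "I": "Susceptible, increased exposure / intermediate",
    "R": "Resistant",
}
CLSI_DISPLAYS = {
    "S": "Susceptible",
    "SDD": "Susceptible dose dependent",
    "I": "Intermediate",
    "R": "Resistant",
    "NS": "Nonsusceptible",
}

# --- MRGN -------------------------------------------------------------------

MRGN_ANSWERS = {
    "2MRGN": loinc("LA33214-0", "2MRGN"),
    "3MRGN": loinc("LA33215-7", "3MRGN"),
    "4MRGN": loinc("LA33216-5", "4MRGN"),
}

# --- canonical value-set URLs ----------------------------------------------

VS = systems.NAMESPACE + "ValueSet/"

#: Published canonical links are used verbatim; the rest live under the
#: documented placeholder namespace.
VS_URLS = {
    "detection-result": VS + "detection-result",
    "positivity-result": VS + "positivity-result",
    "organism": VS + "organism-with-exceptions",
    "colony-count-codes": VS + "colony-count-codes",
    "semiquantitative-result": "https://simplifier.net/medizininformatikinitiative-modullabor/laborergebnis-semiquantitativ",
    "susceptibility-tests": VS + "susceptibility-tests-phenotypic",
    "interpretation-eucast": VS + "susceptibility-interpretation-eucast",
    "interpretation-clsi": VS + "susceptibility-interpretation-clsi",
    "microscopy-methods": VS + "microscopy-methods",
    "staining-methods": VS + "staining-methods",
    "mdro-type": VS + "mdro-type",
    "mrgn-class": VS + "mrgn-classification",
    "resistance-genes": "https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-resistenzgene-loinc",
    "serology": "https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-serologie-immunologie-loinc",
    "virulence": "https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-virulenz-loinc",
    "report-study-type": VS + "report-study-type",
    "avidity-answers": VS + "avidity-answers",
    "assay-components": VS + "molecular-assay-components",
    "score-codes": VS + "microscopy-score-codes",
}
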