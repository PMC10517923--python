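"""Shared fixtures: one valid observation of every kind, built once per test."""

from __future__ import annotations

import pytest

from microfhir import codes, systems
from microfhir.model import (
    AssayComponent,
    Avidity,
    ColonyCount,
    CultureDetection,
    DetectionResult,
    GeneName,
    MDROType,
    Microscopy,
    MicrobiologyReport,
    MolecularDetection,
    MRGNClassification,
    OrganismRef,
    PositivityResult,
    Quantity,
    ResistanceMechanism,
    Score,
    SerologyImmunology,
    SusceptibilityTest,
    VirulenceFactor,
)
from microfhir.terminology import ConceptRef, default_catalog, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_culture(**overrides) -> CultureDetection:
    fields = dict(
        id="culture-1",
        specimen_ref="Specimen/s1",
        result=DetectionResult.detected(),
        organisms=(OrganismRef(concept=codes.snomed(codes.E_COLI)),),
        children=("colony-1", "susc-1"),
    )
    fields.update(overrides)
    return CultureDetection(**fields)


def make_colony_count(**overrides) -> ColonyCount:
    fields = dict(
        id="colony-1",
        code=codes.COLONY_COUNT_CODES[0],
        quantity=Quantity(value=100000.0, unit="/mL"),
    )
    fields.update(overrides)
    return ColonyCount(**fields)


def make_susceptibility(**overrides) -> SusceptibilityTest:
    fields = dict(
        id="susc-1",
        agent_test=codes.loinc("18932-4"),
        mic=Quantity(value=2.0, unit="ug/mL"),
        interpretation="R",
        scheme="EUCAST",
        scheme_version="EUCAST v13.0",
    )
    fields.update(overrides)
    return SusceptibilityTest(**fields)


def make_microscopy(**overrides) -> Microscopy:
    fields = dict(
        id="micro-1",
        result=DetectionResult.detected(),
        method=codes.snomed("104157003"),
        organisms=(OrganismRef(concept=codes.snomed(codes.K_PNEUMONIAE)),),
        morphology_note="Gram-negative rods",
        score=Score(score_code=codes.SCORE_CODES[0], score_value=2),
        quantity=Quantity(value=25.0, unit="1"),
    )
    fields.update(overrides)
    return Microscopy(**fields)


def make_molecular(**overrides) -> MolecularDetection:
    fields = dict(
        id="mol-1",
        result=PositivityResult.positive(),
        organisms=(OrganismRef(concept=codes.snomed("407479009")),),
        assay_components=(
            AssayComponent(component_code=codes.PCR, value=Quantity(value=27.0, unit="1")),
        ),
    )
    fields.update(overrides)
    return MolecularDetection(**fields)


def make_serology(**overrides) -> SerologyImmunology:
    fields = dict(
        id="sero-1",
        test=codes.IMMUNOLOGY_CODE,
        result=PositivityResult.positive(),
        antibody_quantity=Quantity(value=12.5, unit="[arb'U]/mL"),
        avidity=Avidity(value=codes.AVIDITY_HIGH),
    )
    fields.update(overrides)
    return SerologyImmunology(**fields)


def make_mdro(**overrides) -> MDROType:
    fields = dict(id="mdro-1", value=codes.snomed(codes.CARBAPENEM_RESISTANT_PA))
    fields.update(overrides)
    return MDROType(**fields)


def make_mrgn(**overrides) -> MRGNClassification:
    fields = dict(id="mrgn-1", value=codes.MRGN_ANSWERS["3MRGN"])
    fields.update(overrides)
    return MRGNClassification(**fields)


def make_resistance(**overrides) -> ResistanceMechanism:
    fields = dict(
        id="res-1",
        test=codes.GENERIC_GENE_DETECTED,
        result=PositivityResult.positive(),
        gene_name=GeneName(name="blaNDM-1", source="NCBI", identifier="GENE-11189"),
    )
    fields.update(overrides)
    return ResistanceMechanism(**fields)


def make_virulence(**overrides) -> VirulenceFactor:
    fields = dict(
        id="vir-1", test=codes.loinc("99996-3"), result=DetectionResult.detected()
    )
    fields.update(overrides)
    return VirulenceFactor(**fields)


def make_report(**overrides) -> MicrobiologyReport:
    fields = dict(
        id="report-1",
        category=codes.STUDY_TYPES["bacterial"],
        results=("culture-1", "colony-1"),
        conclusion="Carbapenem-resistant E. coli isolated.",
    )
    fields.update(overrides)
    return MicrobiologyReport(**fields)


_BUILDERS = {
    "culture": make_culture,
    "colony_count": make_colony_count,
    "susceptibility": make_susceptibility,
    "microscopy": make_microscopy,
    "molecular": make_molecular,
    "serology": make_serology,
    "mdro_type": make_mdro,
    "mrgn_class": make_mrgn,
    "resistance_mechanism": make_resistance,
    "virulence_factor": make_virulence,
}


@pytest.fixture(scope="session")
def observation_builders():
    return dict(_BUILDERS)


@pytest.fixture(scope="session")
def one_of_each_kind():
    return {kind: build() for kind, build in _BUILDERS.items()}
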