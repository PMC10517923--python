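"""Seeded generators: fixture terminology snapshots and synthetic LIS exports.

The fixture snapshots wire every code the profiles bind into a small toy
hierarchy/parts table so that the whole package runs with zero downloads.
Everything below the named domain/kingdom roots is fictional — fixture codes
must not be mistaken for terminology truth; purely synthetic concepts carry
``[synthetic fixture concept]`` / ``[synthetic fixture code]`` displays.

The LIS generator emulates a tabular laboratory-information-system export:
one row per test result, covering all four diagnostic blocks.  It aims at
structural coverage (every observation kind, both result styles, panels that
exercise the MRGN classifier), not at epidemiological realism.  A single
seed drives the run; each row draws from a counter-derived substream so a
row's content is reproducible independently of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import codes, systems
from .errors import ConfigurationError
from .model import (
    OBSERVATION_KINDS,
    AssayComponent,
    Avidity,
    ColonyCount,
    CultureDetection,
    DetectionResult,
    GeneName,
    MDROType,
    Microscopy,
    MicrobiologyObservation,
    MolecularDetection,
    MRGNClassification,
    OrganismRef,
    PositivityResult,
    Quantity,
    ResistanceMechanism,
    SerologyImmunology,
    SusceptibilityTest,
    VirulenceFactor,
    new_observation,
)
from .mrgn import GROUPS, MRGNInput
from .terminology import ConceptRef, contains, default_catalog, default_registry

__all__ = [
    "SynthConfig",
    "generate_snapshot_fixtures",
    "generate_lab_table",
    "table_to_observations",
    "susceptibility_panels",
    "ConversionResult",
    "RowError",
    "LIS_COLUMNS",
]

# ---------------------------------------------------------------------------
# Fixture snapshot content
# ---------------------------------------------------------------------------

_SYN = " [synthetic fixture concept]"

#: (code, display, parents "|"-joined)
SNOMED_FIXTURE_ROWS: tuple[tuple[str, str, str], ...] = (
    ("138875005", "SNOMED CT Concept (fixture root)", ""),
    # top-level axes
    ("410607006", "Organism (organism)", "138875005"),
    ("362981000", "Qualifier value (qualifier value)", "138875005"),
    ("71388002", "Procedure (procedure)", "138875005"),
    ("363787002", "Observable entity (observable entity)", "138875005"),
    ("4341000179107", "Microbiology report (record artifact)", "138875005"),
    # organisms: included sub-hierarchies
    ("409822003", "Domain Bacteria (organism)", "410607006"),
    ("87172008", "Gram-negative bacterium (organism)", "409822003"),
    ("112283007", "Escherichia coli (organism)", "87172008"),
    ("56415008", "Klebsiella pneumoniae (organism)", "87172008"),
    ("52499004", "Pseudomonas aeruginosa (organism)", "87172008"),
    ("990000301", "Pseudomonas aeruginosa, mucoid phenotype (organism)" + _SYN, "52499004"),
    ("91288006", "Acinetobacter baumannii (organism)", "87172008"),
    ("3092008", "Staphylococcus aureus (organism)", "409822003"),
    ("49872002", "Virus (organism)", "410607006"),
    ("407479009", "Influenza A virus (organism)", "49872002"),
    ("84676004", "Prion (organism)", "410607006"),
    ("414561005", "Kingdom Fungi (organism)", "410607006"),
    ("53326005", "Candida albicans (organism)", "414561005"),
    ("370570004", "Kingdom Protozoa (organism)", "410607006"),
    ("30020004", "Plasmodium falciparum (organism)", "370570004"),
    # organisms: the five excluded sub-hierarchies
    ("243387004", "Domain Archaea (organism)", "410607006"),
    ("990000101", "Toy archaeon (organism)" + _SYN, "243387004"),
    ("387961004", "Kingdom Animalia (organism)", "410607006"),
    ("990000102", "Toy mite (organism)" + _SYN, "387961004"),
    ("414261007", "Kingdom Plantae (organism)", "410607006"),
    ("990000103", "Toy plant (organism)" + _SYN, "414261007"),
    ("770557006", "Kingdom Viridiplantae (organism)", "410607006"),
    ("990000104", "Toy green alga (organism)" + _SYN, "770557006"),
    ("414061000", "Slime mold (organism)", "410607006"),
    ("990000105", "Toy slime mold (organism)" + _SYN, "414061000"),
    # resistant-organism hierarchies
    ("409793007", "Antimicrobial resistant bacteria (organism)", "409822003"),
    ("707497007", "Carbapenem resistant bacteria (organism)", "409793007"),
    ("726492000", "Carbapenem resistant Pseudomonas aeruginosa (organism)", "707497007"),
    ("115329001", "Methicillin resistant Staphylococcus aureus (organism)", "409793007"),
    ("409795000", "Antimicrobial resistant virus (organism)", "49872002"),
    ("409794001", "Antimicrobial resistant fungi (organism)", "414561005"),
    # qualifier values
    ("260373001", "Detected (qualifier value)", "362981000"),
    ("260415000", "Not detected (qualifier value)", "362981000"),
    ("419984006", "Inconclusive (qualifier value)", "362981000"),
    ("10828004", "Positive (qualifier value)", "362981000"),
    ("260408008", "Weakly positive (qualifier value)", "362981000"),
    ("260385009", "Negative (qualifier value)", "362981000"),
    ("75540009", "High (qualifier value)", "362981000"),
    ("62482003", "Low (qualifier value)", "362981000"),
    ("260347006", "Present + out of ++++ (qualifier value)", "362981000"),
    ("260348001", "Present ++ out of ++++ (qualifier value)", "362981000"),
    ("260349009", "Present +++ out of ++++ (qualifier value)", "362981000"),
    ("260350009", "Present ++++ out of ++++ (qualifier value)", "362981000"),
    # procedures
    ("117259009", "Microscopy (procedure)", "71388002"),
    ("58586006", "Microbial ova-parasite examination (procedure)", "71388002"),
    ("117023006", "Thick film peripheral blood smear (procedure)", "71388002"),
    ("408195004", "Thick film for malarial parasites (procedure)", "71388002"),
    ("117024000", "Thin film peripheral blood smear method (procedure)", "71388002"),
    ("67047002", "Microbial wet smear (procedure)", "71388002"),
    ("27318003", "Potassium hydroxide preparation (procedure)", "71388002"),
    ("104157003", "Light microscopy (procedure)", "71388002"),
    ("73512001", "Electron microscopic study (procedure)", "71388002"),
    ("127790008", "Staining method (procedure)", "71388002"),
    ("67122001", "Acid fast stain method (procedure)", "127790008"),
    ("990000201", "Toy Gram stain method (procedure)" + _SYN, "127790008"),
    ("990000202", "Toy fluorescent acid fast stain (procedure)" + _SYN, "67122001"),
    ("398545005", "Nucleic acid assay (procedure)", "71388002"),
    ("9718006", "Polymerase chain reaction analysis (procedure)", "71388002"),
    ("25231800", "Immunology laboratory test (procedure)", "71388002"),
    # observables
    ("77559007", "Immunologic avidity, function (observable entity)", "363787002"),
    ("1285113001", "Type of antimicrobial resistant organism (observable entity)", "363787002"),
)

_SYNC = " [synthetic fixture code]"

#: (code, display, property, method, class, component)
LOINC_FIXTURE_ROWS: tuple[tuple[str, str, str, str, str, str], ...] = (
    ("18725-2", "Microbiology studies (set)", "", "", "PANEL.MICRO", ""),
    ("11475-1", "Microorganism identified in Specimen by Culture",
     "Prid", "Organism specific culture", "MICRO", "Microorganism identified"),
    ("49223-1", "Colony count [#/volume] in Unspecified specimen by Visual count",
     "NCnc", "Visual count", "MICRO", "Colony count"),
    ("564-5", "Colony count [#] in Unspecified specimen by Visual count",
     "Num", "Visual count", "MICRO", "Colony count"),
    ("38436-2", "Colony count [#/mass] in Unspecified specimen by Visual count",
     "NCnc", "Visual count", "MICRO", "Colony count"),
    ("20774-6", "Colony count [Units/volume] in Unspecified specimen by Visual count",
     "ACnc", "Visual count", "MICRO", "Colony count"),
    ("18945-6", "Methicillin [Susceptibility]", "Susc", "", "ABXBACT", "Methicillin"),
    ("18969-1", "Piperacillin [Susceptibility]" + _SYNC, "Susc", "", "ABXBACT", "Piperacillin"),
    ("18893-8", "Ceftazidime [Susceptibility]" + _SYNC, "Susc", "MIC", "ABXBACT", "Ceftazidime"),
    ("18879-7", "Cefotaxime [Susceptibility]" + _SYNC, "Susc", "", "ABXBACT", "Cefotaxime"),
    ("18932-4", "Imipenem [Susceptibility]" + _SYNC, "Susc", "MIC", "ABXBACT", "Imipenem"),
    ("18943-1", "Meropenem [Susceptibility]" + _SYNC, "Susc", "", "ABXBACT", "Meropenem"),
    ("18906-8", "Ciprofloxacin [Susceptibility]" + _SYNC, "Susc", "", "ABXBACT", "Ciprofloxacin"),
    ("99998-9", "Example agent [Susceptibility] by Genotyping" + _SYNC,
     "Susc", "Genotyping", "ABXBACT", "Example agent"),
    ("92253-4", "Microorganism identified in Isolate or Specimen by Molecular genetics method",
     "Prid", "Molgen", "MICRO", "Microorganism identified"),
    ("75371-5", "Bartlett score of Sputum Qualitative by Light microscopy",
     "Nom", "Light microscopy", "MICRO", "Bartlett score"),
    ("43391-2", "Bacterial vaginosis score", "Num", "", "MICRO", "Bacterial vaginosis score"),
    ("99780-9", "Multidrug resistant Gram-negative organism classification [Type]",
     "Type", "", "MICRO", "MRGN classification"),
    ("92251-8", "Microorganism gene detected [Presence] by Molecular method",
     "PrThr", "Molgen", "MICRO", "Microorganism gene"),
    ("92246-8", "Microorganism resistance mutation detected [Presence] by Molecular method",
     "PrThr", "Molgen", "MICRO", "Resistance mutation"),
    ("72421-1", "Vancomycin resistance vanB gene [Presence] by Molecular method",
     "PrThr", "Molgen", "ABXBACT", "vanB gene"),
    ("49617-4", "Vancomycin resistance vanA gene [Presence] by Molecular method" + _SYNC,
     "Prid", "Molgen", "ABXBACT", "vanA gene"),
    ("99997-1", "Carbapenemase blaKPC gene [Presence] by Molecular method" + _SYNC,
     "PrThr", "Molgen", "ABXBACT", "blaKPC gene"),
    ("88603-6", "Adenovirus Ag [Presence] in Lower respiratory specimen by Immunoassay",
     "PrThr", "IA", "MICRO", "Adenovirus Ag"),
    ("5221-7", "Borrelia burgdorferi Ab [Presence] in Serum by Immunofluorescence" + _SYNC,
     "PrThr", "IF", "MICRO", "Borrelia burgdorferi Ab"),
    ("99996-3", "Clostridioides difficile toxin A+B [Presence] in Stool" + _SYNC,
     "PrThr", "IA", "MICRO", "Toxin A+B"),
    ("99995-5", "Shiga toxin [Presence] in Stool" + _SYNC, "Prid", "IA", "MICRO", "Shiga toxin"),
    ("92894-5", "Microbiology - bacterial studies", "", "", "PANEL.MICRO", ""),
    ("92893-7", "Microbiology - viral studies", "", "", "PANEL.MICRO", ""),
    ("96397-5", "Microbiology - mycobacteriology studies", "", "", "PANEL.MICRO", ""),
    ("96398-3", "Microbiology - mycology studies", "", "", "PANEL.MICRO", ""),
    ("92892-9", "Microbiology - parasitic studies", "", "", "PANEL.MICRO", ""),
    ("LA33214-0", "2MRGN", "", "", "LL", ""),
    ("LA33215-7", "3MRGN", "", "", "LL", ""),
    ("LA33216-5", "4MRGN", "", "", "LL", ""),
)

#: Antibiotic-group membership of the fixture susceptibility agents.
AGENTS_BY_GROUP: dict[str, tuple[str, ...]] = {
    "ureidopenicillins": ("18969-1",),
    "cephalosporins": ("18893-8", "18879-7"),
    "carbapenems": ("18932-4", "18943-1"),
    "fluoroquinolones": ("18906-8",),
}
GROUP_BY_AGENT = {a: g for g, agents in AGENTS_BY_GROUP.items() for a in agents}

CARBAPENEMASE_GENE = "99997-1"
RESISTANCE_GENE_CODES = ("72421-1", "49617-4", "99997-1", "92251-8")
VIRULENCE_CODES = ("99996-3", "99995-5")
SEROLOGY_LOINC_CODES = ("88603-6", "5221-7")


def _mem(ref: ConceptRef) -> dict[str, str]:
    return {"code": ref.code, "display": ref.display or ""}


def _valueset_docs() -> list[dict[str, Any]]:
    u = codes.VS_URLS
    return [
        {"name": "detection-result", "url": u["detection-result"], "kind": "extensional",
         "system": systems.SNOMED, "members": [_mem(c) for c in codes.DETECTION_RESULTS]},
        {"name": "positivity-result", "url": u["positivity-result"], "kind": "extensional",
         "system": systems.SNOMED, "members": [_mem(c) for c in codes.POSITIVITY_RESULTS]},
        {"name": "organism", "url": u["organism"], "kind": "intensional",
         "system": systems.SNOMED,
         "include": [{"code": codes.ORGANISM_ROOT}],
         "exclude": list(codes.ORGANISM_EXCLUSIONS)},
        {"name": "colony-count-codes", "url": u["colony-count-codes"], "kind": "extensional",
         "system": systems.LOINC, "members": [_mem(c) for c in codes.COLONY_COUNT_CODES]},
        {"name": "semiquantitative-result", "url": u["semiquantitative-result"],
         "kind": "extensional", "system": systems.SNOMED,
         "members": [_mem(c) for c in codes.SEMIQUANT_RESULTS]},
        {"name": "susceptibility-tests", "url": u["susceptibility-tests"], "kind": "intensional",
         "system": systems.LOINC,
         "parts": [{"part": "property", "op": "equals", "value": "Susc"},
                   {"part": "method", "op": "not-equals", "value": "Genotyping"}]},
        {"name": "interpretation-eucast", "url": u["interpretation-eucast"],
         "kind": "extensional", "system": systems.EUCAST,
         "members": [{"code": c, "display": codes.EUCAST_DISPLAYS[c]}
                     for c in codes.EUCAST_CATEGORIES]},
        {"name": "interpretation-clsi", "url": u["interpretation-clsi"],
         "kind": "extensional", "system": systems.HL7_INTERPRETATION,
         "members": [{"code": c, "display": codes.CLSI_DISPLAYS[c]}
                     for c in codes.CLSI_CATEGORIES]},
        {"name": "microscopy-methods", "url": u["microscopy-methods"], "kind": "extensional",
         "system": systems.SNOMED, "members": [_mem(c) for c in codes.MICROSCOPY_METHODS]},
        {"name": "staining-methods", "url": u["staining-methods"], "kind": "intensional",
         "system": systems.SNOMED, "include": [{"code": codes.STAINING_ROOT}]},
        {"name": "mdro-type", "url": u["mdro-type"], "kind": "intensional",
         "system": systems.SNOMED,
         "include": [{"code": codes.RESISTANT_BACTERIA_ROOT},
                     {"code": codes.RESISTANT_VIRUS_ROOT},
                     {"code": codes.RESISTANT_FUNGI_ROOT}]},
        {"name": "mrgn-class", "url": u["mrgn-class"], "kind": "extensional",
         "system": systems.LOINC, "members": [_mem(c) for c in codes.MRGN_ANSWERS.values()]},
        {"name": "resistance-genes", "url": u["resistance-genes"], "kind": "intensional",
         "system": systems.LOINC,
         "parts": [{"part": "class", "op": "equals", "value": "ABXBACT"},
                   {"part": "property", "op": "in", "value": ["PrThr", "Prid"]}]},
        {"name": "serology", "url": u["serology"], "kind": "extensional",
         "system": systems.LOINC,
         "members": [{"code": c} for c in SEROLOGY_LOINC_CODES]},
        {"name": "virulence", "url": u["virulence"], "kind": "intensional",
         "system": systems.LOINC,
         "parts": [{"part": "class", "op": "equals", "value": "MICRO"},
                   {"part": "property", "op": "in", "value": ["PrThr", "Prid"]}]},
        {"name": "report-study-type", "url": u["report-study-type"], "kind": "extensional",
         "system": systems.LOINC, "members": [_mem(c) for c in codes.STUDY_TYPES.values()]},
        {"name": "avidity-answers", "url": u["avidity-answers"], "kind": "extensional",
         "system": systems.SNOMED,
         "members": [_mem(codes.AVIDITY_HIGH), _mem(codes.AVIDITY_LOW)]},
        {"name": "assay-components", "url": u["assay-components"], "kind": "extensional",
         "system": systems.SNOMED, "members": [_mem(c) for c in codes.ASSAY_COMPONENT_CODES]},
        {"name": "score-codes", "url": u["score-codes"], "kind": "extensional",
         "system": systems.LOINC, "members": [_mem(c) for c in codes.SCORE_CODES]},
    ]


def _eucast_codesystem() -> dict[str, Any]:
    return {
        "resourceType": "CodeSystem",
        "id": "eucast-susceptibility-category",
        "url": systems.EUCAST,
        "status": "draft",
        "content": "complete",
        "caseSensitive": True,
        "description": (
            "Draft code system for EUCAST antimicrobial susceptibility categories; "
            "definitions depend on the EUCAST version in force."
        ),
        "concept": [
            {"code": c, "display": codes.EUCAST_DISPLAYS[c]} for c in codes.EUCAST_CATEGORIES
        ],
    }


def generate_snapshot_fixtures(out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the fixture terminology files; byte-identical across runs.

    Writes ``snomed_mini.tsv`` (hierarchical dialect), ``loinc_mini.tsv``
    (tabular dialect), ``valuesets.yaml`` (the value-set catalog) and
    ``eucast_codesystem.json`` (the drafted EUCAST code system).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    snomed_lines = [f"#system={systems.SNOMED}", "#version=fixture-1",
                    "code\tdisplay\tparent_codes"]
    snomed_lines += ["\t".join(row) for row in SNOMED_FIXTURE_ROWS]
    snomed_path = out_dir / "snomed_mini.tsv"
    snomed_path.write_text("\n".join(snomed_lines) + "\n", encoding="utf-8")

    loinc_lines = [f"#system={systems.LOINC}", "#version=fixture-1",
                   "code\tdisplay\tproperty\tmethod\tclass\tcomponent"]
    loinc_lines += ["\t".join(row) for row in LOINC_FIXTURE_ROWS]
    loinc_path = out_dir / "loinc_mini.tsv"
    loinc_path.write_text("\n".join(loinc_lines) + "\n", encoding="utf-8")

    vs_path = out_dir / "valuesets.yaml"
    vs_path.write_text(
        yaml.safe_dump(_valueset_docs(), sort_keys=False, allow_unicode=True, width=100),
        encoding="utf-8",
    )

    cs_path = out_dir / "eucast_codesystem.json"
    cs_path.write_text(
        json.dumps(_eucast_codesystem(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "snomed_mini": snomed_path,
        "loinc_mini": loinc_path,
        "valuesets": vs_path,
        "eucast_codesystem": cs_path,
    }


# ---------------------------------------------------------------------------
# LIS table generation
# ---------------------------------------------------------------------------

LIS_COLUMNS = [
    "patient_id", "isolate_id", "block", "test_code", "test_system",
    "result_code_or_value", "unit", "interpretation", "scheme", "scheme_version",
    "method_code", "organism_code", "flags",
]

_COVERAGE_ORDER = [
    "culture", "colony_count", "susceptibility", "microscopy", "molecular",
    "serology", "mdro_type", "mrgn_class", "resistance_mechanism", "virulence_factor",
]

_CULTURE_BLOCK_KINDS = ["culture", "colony_count", "susceptibility", "microscopy"]
_FURTHER_KINDS = ["mdro_type", "mrgn_class", "resistance_mechanism", "virulence_factor"]

_SCHEME_VERSIONS = {"EUCAST": "EUCAST v13.0", "CLSI": "CLSI M100-Ed33"}


class SynthConfig(BaseModel):
    """Configuration of a synthetic LIS run (all randomness is seeded)."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_patients: int = 20
    n_results: int = 100
    block_mix: dict[str, float] = {
        "culture": 0.40,
        "molecular": 0.25,
        "serology": 0.20,
        "further_properties": 0.15,
    }
    positivity_rate: float = 0.4
    resistance_rate: float = 0.2
    carbapenemase_rate: float = 0.05
    neonatology_rate: float = 0.05
    fault_injection: bool = False
    fault_rate: float = 0.1
    species_pool: tuple[str, ...] = (
        codes.E_COLI, codes.K_PNEUMONIAE, codes.P_AERUGINOSA, codes.A_BAUMANNII,
    )

    @model_validator(mode="after")
    def _proportions(self) -> "SynthConfig":
        if set(self.block_mix) != {"culture", "molecular", "serology", "further_properties"}:
            raise ValueError("block_mix must cover exactly the four blocks")
        if abs(sum(self.block_mix.values()) - 1.0) > 1e-9:
            raise ValueError("block_mix proportions must sum to 1")
        for name in ("positivity_rate", "resistance_rate", "carbapenemase_rate",
                     "neonatology_rate", "fault_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        return self

    @field_validator("n_patients", "n_results")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("counts must be >= 1")
        return v


def _row_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, index])


def _pick(rng: np.random.Generator, options) -> str:
    return str(options[int(rng.integers(0, len(options)))])


def generate_lab_table(config: SynthConfig) -> pd.DataFrame:
    """Generate a synthetic LIS export; deterministic for a fixed seed.

    The first rows cycle once through all ten observation kinds so every
    kind is exercised whenever ``n_results >= 10``; the remainder follows
    ``block_mix``.  Susceptibility panels always test a carbapenem first so
    panel-level MRGN classification is meaningful.
    """
    rows: list[dict[str, str]] = []
    detected_isolates: list[str] = []
    isolate_species: dict[str, str] = {}
    isolate_neonat: dict[str, bool] = {}
    isolate_susc_count: dict[str, int] = {}

    blocks = list(config.block_mix)
    probs = np.array([config.block_mix[b] for b in blocks])

    for i in range(config.n_results):
        rng = _row_rng(config.seed, i)
        if i < len(_COVERAGE_ORDER):
            kind = _COVERAGE_ORDER[i]
        else:
            block = blocks[int(rng.choice(len(blocks), p=probs))]
            if block == "culture":
                kind = _pick(rng, _CULTURE_BLOCK_KINDS)
            elif block == "molecular":
                kind = "molecular"
            elif block == "serology":
                kind = "serology"
            else:
                kind = _pick(rng, _FURTHER_KINDS)

        row = {c: "" for c in LIS_COLUMNS}
        row["patient_id"] = f"PAT-{int(rng.integers(0, config.n_patients)):03d}"
        row["block"] = OBSERVATION_KINDS[kind].block
        flags: list[str] = []
        fault = config.fault_injection and rng.random() < config.fault_rate

        if kind == "culture":
            row["test_code"], row["test_system"] = "11475-1", systems.LOINC
            detected = rng.random() < config.positivity_rate
            row["result_code_or_value"] = (
                codes.DETECTED.code if detected else codes.NOT_DETECTED.code
            )
            if detected:
                isolate = f"ISO-{len(detected_isolates):04d}"
                species = _pick(rng, config.species_pool)
                row["isolate_id"] = isolate
                row["organism_code"] = species
                detected_isolates.append(isolate)
                isolate_species[isolate] = species
                neonat = rng.random() < config.neonatology_rate
                isolate_neonat[isolate] = neonat
                if neonat:
                    flags.append("neonatology=true")
            if fault:
                row["result_code_or_value"] = codes.POSITIVE.code  # wrong result VS
                flags.append("fault=result-vs")
                row["organism_code"] = ""
                row["isolate_id"] = ""

        elif kind == "colony_count":
            code = _pick(rng, [c.code for c in codes.COLONY_COUNT_CODES])
            row["test_code"], row["test_system"] = code, systems.LOINC
            if detected_isolates:
                row["isolate_id"] = _pick(rng, detected_isolates)
            if rng.random() < 0.3:
                row["result_code_or_value"] = _pick(
                    rng, [c.code for c in codes.SEMIQUANT_RESULTS]
                )
            else:
                row["result_code_or_value"] = str(10 ** int(rng.integers(2, 7)))
                row["unit"] = sorted(codes.COLONY_COUNT_UNITS[code])[0]

        elif kind == "susceptibility":
            if detected_isolates:
                isolate = _pick(rng, detected_isolates)
                row["isolate_id"] = isolate
                n_prev = isolate_susc_count.get(isolate, 0)
                isolate_susc_count[isolate] = n_prev + 1
            else:
                isolate, n_prev = "", 0
            if n_prev == 0:
                agent = _pick(rng, AGENTS_BY_GROUP["carbapenems"])
            else:
                group = list(AGENTS_BY_GROUP)[n_prev % 4]
                agent = _pick(rng, AGENTS_BY_GROUP[group])
            row["test_code"], row["test_system"] = agent, systems.LOINC
            if rng.random() < config.resistance_rate:
                interp = "R"
            elif rng.random() < 0.1:
                interp = "I"
            else:
                interp = "S"
            row["interpretation"] = interp
            scheme = "EUCAST" if rng.random() < 0.7 else "CLSI"
            row["scheme"] = scheme
            row["scheme_version"] = _SCHEME_VERSIONS[scheme]
            if rng.random() < 0.5:
                row["result_code_or_value"] = str(round(float(2 ** int(rng.integers(-2, 7))), 2))
                row["unit"] = "ug/mL" if rng.random() < 0.5 else "mg/L"
            if fault:
                row["scheme_version"] = ""
                flags.append("fault=version-missing")

        elif kind == "microscopy":
            row["test_code"], row["test_system"] = "117259009", systems.SNOMED
            methods = [c.code for c in codes.MICROSCOPY_METHODS] + ["67122001", "990000201"]
            row["method_code"] = _pick(rng, methods)
            detected = rng.random() < config.positivity_rate
            row["result_code_or_value"] = (
                codes.DETECTED.code if detected else codes.NOT_DETECTED.code
            )
            if detected:
                row["organism_code"] = _pick(rng, config.species_pool)
            if fault:
                row["result_code_or_value"] = codes.POSITIVE.code
                flags.append("fault=result-vs")
                row["organism_code"] = ""

        elif kind == "molecular":
            row["test_code"], row["test_system"] = "92253-4", systems.LOINC
            positive = rng.random() < config.positivity_rate
            row["result_code_or_value"] = (
                codes.POSITIVE.code if positive else codes.NEGATIVE.code
            )
            if positive:
                row["organism_code"] = _pick(rng, config.species_pool)
                if rng.random() < 0.5:
                    row["unit"] = "1"
                    flags.append(f"ct={int(rng.integers(15, 40))}")
            if fault:
                row["result_code_or_value"] = codes.DETECTED.code
                flags.append("fault=result-vs")
                row["organism_code"] = ""

        elif kind == "serology":
            if rng.random() < 0.5:
                row["test_code"], row["test_system"] = "25231800", systems.SNOMED
            else:
                row["test_code"], row["test_system"] = (
                    _pick(rng, SEROLOGY_LOINC_CODES), systems.LOINC,
                )
            positive = rng.random() < config.positivity_rate
            row["result_code_or_value"] = (
                codes.POSITIVE.code if positive else codes.NEGATIVE.code
            )
            if positive and rng.random() < 0.3:
                flags.append("avidity=" + ("high" if rng.random() < 0.5 else "low"))
            if fault:
                row["result_code_or_value"] = codes.DETECTED.code
                flags.append("fault=result-vs")

        elif kind == "mdro_type":
            row["test_code"], row["test_system"] = "1285113001", systems.SNOMED
            row["result_code_or_value"] = _pick(
                rng, ["707497007", "726492000", "115329001"]
            )

        elif kind == "mrgn_class":
            row["test_code"], row["test_system"] = "99780-9", systems.LOINC
            row["result_code_or_value"] = _pick(
                rng, [c.code for c in codes.MRGN_ANSWERS.values()]
            )

        elif kind == "resistance_mechanism":
            positive = rng.random() < config.positivity_rate
            carb = positive and rng.random() < config.carbapenemase_rate
            gene = CARBAPENEMASE_GENE if carb else _pick(rng, RESISTANCE_GENE_CODES)
            row["test_code"], row["test_system"] = gene, systems.LOINC
            row["result_code_or_value"] = (
                codes.POSITIVE.code if positive else codes.NEGATIVE.code
            )
            if gene == CARBAPENEMASE_GENE and positive:
                flags.append("carbapenemase=true")
                if detected_isolates:
                    row["isolate_id"] = _pick(rng, detected_isolates)
            if gene == "92251-8":
                flags.append("gene_name=blaNDM-1,gene_source=NCBI,gene_id=GENE-11189")
            if fault:
                row["result_code_or_value"] = codes.DETECTED.code
                flags.append("fault=result-vs")

        else:  # virulence_factor
            row["test_code"], row["test_system"] = _pick(rng, VIRULENCE_CODES), systems.LOINC
            detected = rng.random() < config.positivity_rate
            row["result_code_or_value"] = (
                codes.DETECTED.code if detected else codes.NOT_DETECTED.code
            )
            if fault:
                row["result_code_or_value"] = codes.POSITIVE.code
                flags.append("fault=result-vs")

        row["flags"] = ";".join(flags)
        rows.append(row)

    return pd.DataFrame(rows, columns=LIS_COLUMNS)


# ---------------------------------------------------------------------------
# Table → observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RowError:
    index: int
    message: str


@dataclass
class ConversionResult:
    observations: list[MicrobiologyObservation] = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)


_FV_KINDS = {
    ("11475-1", systems.LOINC): "culture",
    ("117259009", systems.SNOMED): "microscopy",
    ("92253-4", systems.LOINC): "molecular",
    ("25231800", systems.SNOMED): "serology",
    ("1285113001", systems.SNOMED): "mdro_type",
    ("99780-9", systems.LOINC): "mrgn_class",
}


def kind_for_test_code(code: str, system: str) -> Optional[str]:
    """Infer the observation kind from a LIS test code."""
    if (code, system) in _FV_KINDS:
        return _FV_KINDS[(code, system)]
    if system != systems.LOINC:
        return None
    if code in {c.code for c in codes.COLONY_COUNT_CODES}:
        return "colony_count"
    registry, catalog = default_registry(), default_catalog()
    ref = ConceptRef(system=system, code=code)
    if code not in registry.get(systems.LOINC):
        return None
    if contains(catalog.resolve("susceptibility-tests"), ref, registry):
        return "susceptibility"
    if code in {c.code for c in codes.GENERIC_RESISTANCE_CODES} or contains(
        catalog.resolve("resistance-genes"), ref, registry
    ):
        return "resistance_mechanism"
    if contains(catalog.resolve("serology"), ref, registry):
        return "serology"
    if contains(catalog.resolve("virulence"), ref, registry):
        return "virulence_factor"
    return None


def _parse_flags(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in (raw or "").split(";"):
        if "=" in part:
            k, _, v = part.partition("=")
            out[k.strip()] = v.strip()
    return out


def _row_payload(kind: str, row: dict[str, str], obs_id: str) -> dict[str, Any]:
    """Build the typed field map for one LIS row."""
    flags = _parse_flags(row.get("flags", ""))
    snomed_ref = lambda c: ConceptRef(system=systems.SNOMED, code=c)  # noqa: E731
    loinc_ref = lambda c: ConceptRef(system=systems.LOINC, code=c)  # noqa: E731
    result_code = row.get("result_code_or_value", "")

    if kind == "culture":
        payload: dict[str, Any] = {
            "id": obs_id,
            "result": DetectionResult.model_construct(value=snomed_ref(result_code)),
        }
        if row.get("organism_code"):
            payload["organisms"] = (
                OrganismRef.model_construct(concept=snomed_ref(row["organism_code"])),
            )
        if row.get("patient_id"):
            payload["specimen_ref"] = f"Specimen/{row['patient_id']}"
        return payload
    if kind == "colony_count":
        payload = {"id": obs_id, "code": loinc_ref(row["test_code"])}
        if row.get("unit"):
            payload["quantity"] = Quantity(value=float(result_code), unit=row["unit"])
        else:
            payload["semiquantitative"] = snomed_ref(result_code)
        return payload
    if kind == "susceptibility":
        payload = {
            "id": obs_id,
            "agent_test": loinc_ref(row["test_code"]),
            "scheme": row.get("scheme") or "EUCAST",
            "scheme_version": row.get("scheme_version", ""),
        }
        if row.get("interpretation"):
            payload["interpretation"] = row["interpretation"]
        if row.get("unit"):
            payload["mic"] = Quantity(value=float(result_code), unit=row["unit"])
        return payload
    if kind == "microscopy":
        payload = {
            "id": obs_id,
            "result": DetectionResult.model_construct(value=snomed_ref(result_code)),
            "method": snomed_ref(row["method_code"] or "104157003"),
        }
        if row.get("organism_code"):
            payload["organisms"] = (
                OrganismRef.model_construct(concept=snomed_ref(row["organism_code"])),
            )
        return payload
    if kind == "molecular":
        payload = {
            "id": obs_id,
            "result": PositivityResult.model_construct(value=snomed_ref(result_code)),
        }
        if row.get("organism_code"):
            payload["organisms"] = (
                OrganismRef.model_construct(concept=snomed_ref(row["organism_code"])),
            )
        if "ct" in flags:
            payload["assay_components"] = (
                AssayComponent(
                    component_code=codes.PCR,
                    value=Quantity(value=float(flags["ct"]), unit="1"),
                ),
            )
        return payload
    if kind == "serology":
        test_system = row.get("test_system") or systems.SNOMED
        payload = {
            "id": obs_id,
            "test": ConceptRef(system=test_system, code=row["test_code"]),
            "result": PositivityResult.model_construct(value=snomed_ref(result_code)),
        }
        if flags.get("avidity") == "high":
            payload["avidity"] = Avidity(value=codes.AVIDITY_HIGH)
        elif flags.get("avidity") == "low":
            payload["avidity"] = Avidity(value=codes.AVIDITY_LOW)
        return payload
    if kind == "mdro_type":
        return {"id": obs_id, "value": snomed_ref(result_code)}
    if kind == "mrgn_class":
        return {"id": obs_id, "value": loinc_ref(result_code)}
    if kind == "resistance_mechanism":
        payload = {
            "id": obs_id,
            "test": loinc_ref(row["test_code"]),
            "result": PositivityResult.model_construct(value=snomed_ref(result_code)),
        }
        if "gene_name" in flags:
            payload["gene_name"] = GeneName(
                name=flags["gene_name"],
                source=flags.get("gene_source", "NCBI"),  # type: ignore[arg-type]
                identifier=flags.get("gene_id", flags["gene_name"]),
            )
        return payload
    # virulence_factor
    return {
        "id": obs_id,
        "test": loinc_ref(row["test_code"]),
        "result": DetectionResult.model_construct(value=snomed_ref(result_code)),
    }


def table_to_observations(table: pd.DataFrame) -> ConversionResult:
    """Convert an LIS table to observations, one per row.

    Colony-count and susceptibility rows are wired to their culture row via
    the isolate-id column (the culture gains ``children`` / hasMember links).
    Row-level problems (unknown test code, dangling isolate reference) are
    collected, never fatal.  Rows whose payload violates a domain invariant
    (fault-injected exports) still yield an observation — built without
    validation — so the profile validator can flag them downstream.
    """
    missing = [c for c in LIS_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"LIS table is missing columns: {missing}")

    result = ConversionResult()
    culture_by_isolate: dict[str, int] = {}  # isolate -> index into observations
    child_links: dict[str, list[str]] = {}

    records = table.fillna("").astype(str).to_dict("records")
    for i, row in enumerate(records):
        obs_id = f"obs-{i:05d}"
        kind = kind_for_test_code(row["test_code"], row["test_system"])
        if kind is None:
            result.errors.append(
                RowError(i, f"unknown test code {row['test_code']!r} ({row['test_system']})")
            )
            continue
        try:
            payload = _row_payload(kind, row, obs_id)
        except (ValueError, KeyError) as exc:
            result.errors.append(RowError(i, f"unparseable row: {exc}"))
            continue
        cls = OBSERVATION_KINDS[kind].cls
        try:
            obs = new_observation(kind, payload)
        except Exception:
            obs = cls.model_construct(**payload)  # invalid on purpose: caught downstream
        result.observations.append(obs)

        isolate = row.get("isolate_id", "")
        if isolate:
            if kind == "culture":
                culture_by_isolate[isolate] = len(result.observations) - 1
            elif kind in ("colony_count", "susceptibility"):
                child_links.setdefault(isolate, []).append(obs_id)

    for isolate, children in child_links.items():
        idx = culture_by_isolate.get(isolate)
        if idx is None:
            rows_str = ", ".join(children)
            result.errors.append(
                RowError(-1, f"isolate {isolate!r} of rows [{rows_str}] has no culture row")
            )
            continue
        culture = result.observations[idx]
        assert isinstance(culture, CultureDetection)
        if culture.result.is_detected:
            from .model import link_culture_children

            result.observations[idx] = link_culture_children(culture, children)
    return result


def susceptibility_panels(table: pd.DataFrame) -> dict[str, MRGNInput]:
    """Aggregate susceptibility rows per isolate into MRGN classifier inputs.

    Untested groups are marked not-tested; when a group is tested repeatedly
    the worst category wins (R > I > S).  Carbapenemase detection and the
    neonatology flag are taken from resistance-mechanism / culture rows of
    the same isolate.
    """
    severity = {"not-tested": 0, "S": 1, "I": 2, "R": 3}
    species: dict[str, str] = {}
    neonat: dict[str, bool] = {}
    carb: dict[str, bool] = {}
    groups: dict[str, dict[str, str]] = {}

    records = table.fillna("").astype(str).to_dict("records")
    for row in records:
        isolate = row.get("isolate_id", "")
        if not isolate:
            continue
        flags = _parse_flags(row.get("flags", ""))
        if row["test_code"] == "11475-1":
            if row.get("organism_code"):
                species[isolate] = row["organism_code"]
            neonat[isolate] = flags.get("neonatology") == "true"
        elif flags.get("carbapenemase") == "true":
            carb[isolate] = True
        elif row["test_code"] in GROUP_BY_AGENT and row.get("interpretation"):
            group = GROUP_BY_AGENT[row["test_code"]]
            mrgn_group = {
                "ureidopenicillins": "ureidopenicillins",
                "cephalosporins": "cephalosporins_3_4",
                "carbapenems": "carbapenems",
                "fluoroquinolones": "fluoroquinolones",
            }[group]
            panel = groups.setdefault(isolate, {g: "not-tested" for g in GROUPS})
            interp = row["interpretation"] if row["interpretation"] in ("S", "I", "R") else "S"
            if severity[interp] > severity[panel[mrgn_group]]:
                panel[mrgn_group] = interp

    out: dict[str, MRGNInput] = {}
    for isolate, panel in groups.items():
        out[isolate] = MRGNInput(
            species=ConceptRef(
                system=systems.SNOMED, code=species.get(isolate, codes.E_COLI)
            ),
            class_results=panel,
            carbapenemase_detected=carb.get(isolate, False),
            neonatology=neonat.get(isolate, False),
        )
    return out
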