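# microfhir

A working implementation of a standardized microbiology core data set:
typed laboratory results for the four diagnostic blocks of clinical
microbiology — **culture** (detection, colony count, susceptibility,
microscopy), **molecular diagnostics**, **immunology/serology**, and
**further organism properties** (MDRO type, MRGN class, resistance
mechanisms, virulence factors) — with conformant **FHIR R4 JSON**
serialization, terminology-driven **profile validation** against
SNOMED CT / LOINC / UCUM bindings, intensional and extensional **value-set
evaluation**, and the **KRINKO MRGN** multidrug-resistance classifier.

It is aimed at people who move microbiology results between laboratory
information systems and FHIR-based research infrastructures: data
engineers at hospital data integration centers, infection-control tooling
authors, and terminology folks who want an executable form of the profile
bindings instead of a PDF.

Everything runs offline.  Real SNOMED CT and LOINC releases are licensed
and never redistributed; the package bundles *fixture snapshots* — tiny
hand-editable TSV files wiring every code the profiles bind into a toy
hierarchy/parts table.  Fixture codes below the named domain/kingdom roots
are fictional and must not be mistaken for terminology truth.  Real
terminology releases plug in through the same two-file snapshot format.

## The model in brief

Each examination is one FHIR `Observation`: the test goes to
`Observation.code`, the primary result to `Observation.value[x]`,
additional results of the same examination (organism name, cycle
threshold, scores, gene names, avidity) to `Observation.component[]`, the
method to `Observation.method`, and the links from a detected culture to
its characterizing observations (colony count, susceptibility tests) to
`Observation.hasMember`.  Every observation carries the fixed category
coding LOINC `18725-2` *Microbiology studies (set)*; a `DiagnosticReport`
groups observations under one of five study types.  No FHIR extensions are
used anywhere.

Value sets come in two flavours: extensional (enumerated codes, e.g. the
four colony-count codes) and intensional (rule-defined).  Hierarchical
rules are the ECL subset `<X` / `<<X` minus excluded subtrees — e.g. the
organism set is `<410607006 |Organism|` minus the Archaea, Animalia,
Plantae, Viridiplantae and slime-mold subtrees.  Tabular (LOINC-style)
rules constrain the parts Property/Method/Class — e.g. susceptibility
tests are `Property = Susc and Method ≠ Genotyping`.

The MRGN classifier rates a Gram-negative isolate against four antibiotic
groups (ureidopenicillins, 3rd/4th-gen cephalosporins, carbapenems,
fluoroquinolones): resistance to 2/3/4 groups gives 2MRGN/3MRGN/4MRGN
(2MRGN only in neonatology); a detected carbapenemase always gives 4MRGN,
as does carbapenem resistance alone — except for *P. aeruginosa*.

## Worked example

```python
from microfhir.mrgn import MRGNInput, classify
from microfhir.terminology import ConceptRef
from microfhir import codes, systems

isolate = MRGNInput(
    species=ConceptRef(system=systems.SNOMED, code=codes.E_COLI),
    class_results={
        "ureidopenicillins": "R",
        "cephalosporins_3_4": "R",
        "carbapenems": "S",
        "fluoroquinolones": "R",
    },
    carbapenemase_detected=False,
)
result = classify(isolate)
print(result.category, result.answer_code.code, list(result.rationale))
```

prints

```
3MRGN LA33215-7 ['three-groups-resistant-3mrgn']
```

— three of the four groups are resistant, so the isolate is 3MRGN, encoded
with the LOINC answer code `LA33215-7` of observation `99780-9`.

The same library drives a CLI.  Generating a seeded synthetic LIS export,
converting it to FHIR and validating it:

```console
$ microfhir generate --seed 1 --out-dir demo --n-results 100
wrote snapshots/, lis_table.csv (100 rows) and observations.ndjson (100 resources) to demo
$ microfhir validate demo/observations.ndjson
100 resources, 0 issues (0 errors)
$ microfhir expand colony-count-codes
http://loinc.org    20774-6    Colony count [Units/volume] in Unspecified specimen by Visual count
http://loinc.org    38436-2    Colony count [#/mass] in Unspecified specimen by Visual count
http://loinc.org    49223-1    Colony count [#/volume] in Unspecified specimen by Visual count
http://loinc.org    564-5      Colony count [#] in Unspecified specimen by Visual count
4 codes in https://example.org/fhir/microbiology/ValueSet/colony-count-codes
```

Exit codes are fixed: 0 success, 1 validation errors present, 2 usage or
configuration error.

## Layout

| module | role |
| --- | --- |
| `microfhir.terminology` | snapshots, value sets, `expand`/`contains`, descendant queries |
| `microfhir.model` | the ten observation kinds + report, construction rules |
| `microfhir.fhir_io` | FHIR R4 JSON emission/parsing, report bundles, canonical dumps |
| `microfhir.validation` | rule catalog and profile validator |
| `microfhir.mrgn` | KRINKO MRGN classifier |
| `microfhir.synth` | fixture snapshot writer, seeded synthetic LIS generator |
| `microfhir.cli` | `microfhir` command: validate / convert / classify-mrgn / expand / generate |

See `docs/methods.md` for the modelling decisions, parameters and known
limitations.
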