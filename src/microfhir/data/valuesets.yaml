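- name: detection-result
  url: https://example.org/fhir/microbiology/ValueSet/detection-result
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '260373001'
    display: Detected (qualifier value)
  - code: '260415000'
    display: Not detected (qualifier value)
  - code: '419984006'
    display: Inconclusive (qualifier value)
- name: positivity-result
  url: https://example.org/fhir/microbiology/ValueSet/positivity-result
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '10828004'
    display: Positive (qualifier value)
  - code: '260408008'
    display: Weakly positive (qualifier value)
  - code: '260385009'
    display: Negative (qualifier value)
  - code: '419984006'
    display: Inconclusive (qualifier value)
- name: organism
  url: https://example.org/fhir/microbiology/ValueSet/organism-with-exceptions
  kind: intensional
  system: http://snomed.info/sct
  include:
  - code: '410607006'
  exclude:
  - '243387004'
  - '387961004'
  - '414261007'
  - '770557006'
  - '414061000'
- name: colony-count-codes
  url: https://example.org/fhir/microbiology/ValueSet/colony-count-codes
  kind: extensional
  system: http://loinc.org
  members:
  - code: 49223-1
    display: Colony count [#/volume] in Unspecified specimen by Visual count
  - code: 564-5
    display: Colony count [#] in Unspecified specimen by Visual count
  - code: 38436-2
    display: Colony count [#/mass] in Unspecified specimen by Visual count
  - code: 20774-6
    display: Colony count [Units/volume] in Unspecified specimen by Visual count
- name: semiquantitative-result
  url: https://simplifier.net/medizininformatikinitiative-modullabor/laborergebnis-semiquantitativ
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '260347006'
    display: Present + out of ++++ (qualifier value)
  - code: '260348001'
    display: Present ++ out of ++++ (qualifier value)
  - code: '260349009'
    display: Present +++ out of ++++ (qualifier value)
  - code: '260350009'
    display: Present ++++ out of ++++ (qualifier value)
- name: susceptibility-tests
  url: https://example.org/fhir/microbiology/ValueSet/susceptibility-tests-phenotypic
  kind: intensional
  system: http://loinc.org
  parts:
  - part: property
    op: equals
    value: Susc
  - part: method
    op: not-equals
    value: Genotyping
- name: interpretation-eucast
  url: https://example.org/fhir/microbiology/ValueSet/susceptibility-interpretation-eucast
  kind: extensional
  system: https://example.org/fhir/microbiology/CodeSystem/eucast-susceptibility-category
  members:
  - code: S
    display: Susceptible
  - code: I
    display: Susceptible, increased exposure / intermediate
  - code: R
    display: Resistant
- name: interpretation-clsi
  url: https://example.org/fhir/microbiology/ValueSet/susceptibility-interpretation-clsi
  kind: extensional
  system: http://terminology.hl7.org/CodeSystem/v3-ObservationInterpretation
  members:
  - code: S
    display: Susceptible
  - code: SDD
    display: Susceptible dose dependent
  - code: I
    display: Intermediate
  - code: R
    display: Resistant
  - code: NS
    display: Nonsusceptible
- name: microscopy-methods
  url: https://example.org/fhir/microbiology/ValueSet/microscopy-methods
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '58586006'
    display: Microbial ova-parasite examination (procedure)
  - code: '117023006'
    display: Thick film peripheral blood smear (procedure)
  - code: '408195004'
    display: Thick film for malarial parasites (procedure)
  - code: '117024000'
    display: Thin film peripheral blood smear method (procedure)
  - code: '67047002'
    display: Microbial wet smear (procedure)
  - code: '27318003'
    display: Potassium hydroxide preparation (procedure)
  - code: '104157003'
    display: Light microscopy (procedure)
  - code: '73512001'
    display: Electron microscopic study (procedure)
- name: staining-methods
  url: https://example.org/fhir/microbiology/ValueSet/staining-methods
  kind: intensional
  system: http://snomed.info/sct
  include:
  - code: '127790008'
- name: mdro-type
  url: https://example.org/fhir/microbiology/ValueSet/mdro-type
  kind: intensional
  system: http://snomed.info/sct
  include:
  - code: '409793007'
  - code: '409795000'
  - code: '409794001'
- name: mrgn-class
  url: https://example.org/fhir/microbiology/ValueSet/mrgn-classification
  kind: extensional
  system: http://loinc.org
  members:
  - code: LA33214-0
    display: 2MRGN
  - code: LA33215-7
    display: 3MRGN
  - code: LA33216-5
    display: 4MRGN
- name: resistance-genes
  url: https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-resistenzgene-loinc
  kind: intensional
  system: http://loinc.org
  parts:
  - part: class
    op: equals
    value: ABXBACT
  - part: property
    op: in
    value:
    - PrThr
    - Prid
- name: serology
  url: https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-serologie-immunologie-loinc
  kind: extensional
  system: http://loinc.org
  members:
  - code: 88603-6
  - code: 5221-7
- name: virulence
  url: https://simplifier.net/medizininformatik-initiative-modul-mikrobiologie/mii-vs-mikrobio-virulenz-loinc
  kind: intensional
  system: http://loinc.org
  parts:
  - part: class
    op: equals
    value: MICRO
  - part: property
    op: in
    value:
    - PrThr
    - Prid
- name: report-study-type
  url: https://example.org/fhir/microbiology/ValueSet/report-study-type
  kind: extensional
  system: http://loinc.org
  members:
  - code: 92894-5
    display: Microbiology - bacterial studies
  - code: 92893-7
    display: Microbiology - viral studies
  - code: 96397-5
    display: Microbiology - mycobacteriology studies
  - code: 96398-3
    display: Microbiology - mycology studies
  - code: 92892-9
    display: Microbiology - parasitic studies
- name: avidity-answers
  url: https://example.org/fhir/microbiology/ValueSet/avidity-answers
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '75540009'
    display: High (qualifier value)
  - code: '62482003'
    display: Low (qualifier value)
- name: assay-components
  url: https://example.org/fhir/microbiology/ValueSet/molecular-assay-components
  kind: extensional
  system: http://snomed.info/sct
  members:
  - code: '398545005'
    display: Nucleic acid assay (procedure)
  - code: '9718006'
    display: Polymerase chain reaction analysis (procedure)
- name: score-codes
  url: https://example.org/fhir/microbiology/ValueSet/microscopy-score-codes
  kind: extensional
  system: http://loinc.org
  members:
  - code: 75371-5
    display: Bartlett score of Sputum Qualitative by Light microscopy
  - code: 43391-2
    display: Bacterial vaginosis score
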