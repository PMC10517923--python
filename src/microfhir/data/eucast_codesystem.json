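{
  "caseSensitive": true,
  "concept": [
    {
      "code": "S",
      "display": "Susceptible"
    },
    {
      "code": "I",
      "display": "Susceptible, increased exposure / intermediate"
    },
    {
      "code": "R",
      "display": "Resistant"
    }
  ],
  "content": "complete",
  "description": "Draft code system for EUCAST antimicrobial susceptibility categories; definitions depend on the EUCAST version in force.",
  "id": "eucast-susceptibility-category",
  "resourceType": "CodeSystem",
  "status": "draft",
  "url": "https://example.org/fhir/microbiology/CodeSystem/eucast-susceptibility-category"
}
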