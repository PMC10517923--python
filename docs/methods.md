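# Methods

This note documents how the package models microbiology results, which
choices were open and how they were decided, what the synthetic generator
does and does not emulate, and the known limitations.

## Information model

Laboratory examinations are grouped into three main diagnostic blocks —
culture (including microscopy), molecular diagnostics, and
immunology/serology — plus a *further properties* group for observations
that characterize an already-detected organism (MDRO type, MRGN class,
resistance mechanism, virulence factor).  The registry
(`model.OBSERVATION_KINDS`) enumerates ten observation kinds plus one
report type; each kind belongs to exactly one block.

Two qualitative result styles exist and are deliberately kept apart as a
per-kind attribute:

* **detection** (detected `260373001` / not detected `260415000` /
  inconclusive `419984006`) for culture, microscopy and virulence-factor
  observations;
* **positivity** (positive `10828004` / weakly positive `260408008` /
  negative `260385009` / inconclusive `419984006`) for molecular,
  serology and resistance-mechanism observations.

Mixing the two (e.g. a "detected" code on a molecular result) is a
construction error and a validation error (`result-vs-mismatch`).

Other construction invariants worth naming:

* an organism component implies a *detected* culture result — a named
  organism on a negative culture is meaningless, so this is an error, not
  a warning;
* a reported susceptibility category requires a non-empty standard's
  version (`susc-version-required`), because EUCAST and CLSI have
  redefined the categories over the years and a bare "I" is ambiguous;
* colony counts are a choice type: a numeric quantity *or* a
  semi-quantitative code, never both, and the unit must match the chosen
  code's unit class (`/mL`, dimensionless, `/g`, `[CFU]/mL`);
* generic gene/mutation codes (`92251-8`, `92246-8`) require the gene
  name, carried as a component pointing into a genomics database (NCBI or
  EMBL-EBI), since no specific LOINC code exists in that case.

Patient, encounter and specimen are opaque reference strings: those
resources belong to neighbouring modules of the wider data set and are
not modelled here.  Identifiers are caller-supplied; the library never
invents UUIDs outside the seeded synthetic module (and the deterministic
urn:uuid references inside report bundles, derived by UUIDv5 from the
resource id).

One terminological oddity is preserved on purpose: the generic immunology
procedure code is carried verbatim as the 8-digit `25231800`, exactly as
published, rather than "corrected" to a plausible longer SNOMED code.

## Terminology engine

Snapshots are two TSV dialects: *hierarchical* (code, display,
`|`-separated parents; an acyclic is-a graph, checked at load) and
*tabular* (code, display, and the LOINC-style parts Property, Method,
Class, Component).  The rule language for intensional value sets is
exactly what the profiles need and nothing more:

* hierarchical — union of include roots, each `<` (strict descendants) or
  `<<` (descendant-or-self), minus excluded subtrees.  **Exclusions are
  descendant-or-self and dominate inclusions**: whole sub-groups were
  ruled out of the organism set, so the exclusion root itself disappears.
* tabular — a conjunction of part constraints (`equals`, `not-equals`,
  `in`), matched case-insensitively ("susc" and "Susc" both appear in the
  wild).

Full ECL, description-logic classification and terminology-server
protocols are out of scope.  `contains()` answers membership without
materializing expansions; for intensional sets an unknown code *raises*
rather than returning false, so fixture/snapshot mismatches surface
immediately instead of silently passing validation.

Open points decided here: the organism value set removes exactly the five
named subtrees (Archaea, Animalia, Plantae, Viridiplantae, slime molds),
with no additional depth constraint; the susceptibility rule applies only
the two published constraints (Property = Susc, Method ≠ Genotyping) and
does not additionally exclude non-quantitative codes.  The tabular
virulence rule (Class = MICRO, Property ∈ {PrThr, Prid}) is intentionally
broad — on the fixture it also matches some detection and serology codes;
tightening it would mean inventing constraints the binding does not state.

## FHIR mapping

Serialization targets FHIR R4 JSON only.  The element mapping is the
profiled Observation pattern described in the README.  Decisions that were
genuinely open:

* **Interpretation systems.**  S/I/R is emitted with a self-defined draft
  EUCAST code-system URI (shipped as `data/eucast_codesystem.json`),
  because the category definitions are version-bound to EUCAST and no
  published FHIR code system exists for them; the five-value CLSI-style
  set (S, SDD, I, R, NS) uses the HL7 v3 ObservationInterpretation
  system.  The scheme is recoverable from the coding system alone.
* **Component codes.**  The profiles fix component codes only for avidity
  (`77559007`), scores (`75371-5`, `43391-2`) and molecular assay
  procedures (`398545005`, `9718006`).  The remaining component slots
  (organism name, free numeric results, gene name) use a small local
  component-role code system under the package namespace; every coding in
  emitted JSON therefore carries an explicit system URI.
* **Canonical URLs.**  The four published simplifier.net value-set links
  are used verbatim as catalog keys; everything else (profiles, remaining
  value sets, the EUCAST and component-role code systems) lives under a
  documented `https://example.org/fhir/microbiology/` placeholder
  namespace.
* **Report category.**  The DiagnosticReport category carries the fixed
  report coding `4341000179107` and the LOINC study-type code as two
  codings in *one* CodeableConcept; one-vs-two CodeableConcepts is not
  fixed anywhere, so the more compact form was chosen and is isolated in
  one builder function.
* Serialization is canonical (sorted keys, compact separators), so equal
  objects produce byte-identical JSON; no extensions are ever emitted,
  and a test scans the whole synthetic corpus for `"extension"` keys.

Parsing (`from_fhir`) dispatches on `meta.profile`, falling back to the
fixed/enumerated `Observation.code` values; `strict=False` returns a
best-effort object (built without validation when necessary) together
with the validator's issue list.

## Validation

The validator is a hand-compiled rule set, not a StructureDefinition
engine.  Rule classes: fixed values, value-set memberships (via
`terminology.contains`), choice-type exclusivity, the mandatory-version
rule, the UCUM whitelist per context, hasMember target kinds (applied only
when sibling resources are supplied, since references cannot be resolved
otherwise), and the generic-gene-component rule.  All profile-derived
constraints are errors; unknown extra elements are warnings because FHIR
resources are open; missing *optional* elements are never issues — the
profiles deliberately fix few mandatory elements, and the validator
respects that.  `validate` is pure: problems come back as a list of
issues sorted by (path, rule id), and the same input always yields the
same list.  The rule catalog is the contract: every rule the validator
can emit appears in `rule_catalog()`, and the test suite's mutation
harness covers each catalog rule with a targeted single-element fault.

## MRGN classifier

Rules are applied in a fixed order, each firing recorded in the
rationale: (1) carbapenemase detected → 4MRGN regardless of phenotype;
(2) carbapenems R and species not *P. aeruginosa* → 4MRGN; (3) count of
groups tested R: 4 → 4MRGN, 3 → 3MRGN, 2 → 2MRGN only with the
neonatology flag, else no category.

Decisions: **"I" does not count as resistant** for the group count — the
category names resistance, and "I" means intermediate or
susceptible-increased exposure; because local practice varies this is
configurable (`count_intermediate_as_resistant`).  **Not-tested counts as
not resistant** and attaches a warning, since under-testing can
under-classify.  The *P. aeruginosa* exception is decided by a descendant
test against the *P. aeruginosa* concept in the active snapshot, so
subtype codes inherit the exception.  A species outside the Gram-negative
set (or unknown to the snapshot) yields a warning but still a
classification.  Two resistant groups without the neonatology flag give
category `none` with a rationale entry naming the restriction.

Known gap: the special phenotype-based 3MRGN rule for *P. aeruginosa*
("only one of four groups still active") that exists in the full KRINKO
scheme is not implemented — only the rules stated above are; a
carbapenem-resistant-only *P. aeruginosa* therefore classifies as `none`
here.  Correctness is checked by exhaustive equivalence with a
brute-force oracle over the full 4⁴ × flags × species grid, a frozen
truth-table regression fixture, and monotonicity/dominance properties.

## Synthetic data

The generator emulates a tabular LIS export: one row per test result with
specimen/test/organism/value/unit/interpretation columns, covering all
four blocks.  Defaults (chosen once as plausible for a mixed clinical
workload, not fitted to any dataset): 100 results over 20 patients, block
mix 40 % culture / 25 % molecular / 20 % serology / 15 % further
properties, positivity rate 0.4, per-group resistance rate 0.2,
carbapenemase rate 0.05, neonatology rate 0.05.  The first ten rows cycle
deterministically through all ten kinds so structural coverage holds from
50 results down to 10; susceptibility panels always test a carbapenem
first, so panel-level MRGN classification is well-defined whenever a
panel exists.  A single seed drives the run; each row draws from a
counter-derived substream (`default_rng([seed, row_index])`), keeping
rows reproducible independently of one another.  Optional fault injection
corrupts a configurable fraction of rows (wrong-value-set result codes,
missing scheme versions) for validator testing; corrupted rows still
become observations — built without validation — precisely so the
validator can flag them downstream.

What the generator does **not** emulate: real prevalence or AMR
epidemiology, specimen types, timing, free-text, device data, or
realistic LOINC coverage.  Green tests therefore demonstrate structural
and semantic conformance machinery, not statistical realism; applying the
package to real exports still requires site-specific code mapping.

Problem sizes used by the test suite and acceptance script — 4⁴ × 8 grid
points for the classifier, 1 000 synthetic observations for the
round-trip/coherence corpus, 100–300-row tables elsewhere — were chosen
as the smallest sizes that exercise every code path exhaustively.

## Limitations

* Not a general FHIR validator; only the hand-compiled profile rules.
* No XML, no REST client/server, no terminology-service protocol.
* No antimicrobial-therapy, demographic or encounter modelling; no
  molecular-typing observation kind; no MIC→category breakpoint tables
  (interpretation is an input, not computed).
* Bundled snapshots are fixtures: complete for the bound codes, toy
  everywhere else.
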