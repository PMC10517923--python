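"""MRGN classifier: rule sentences, exhaustive oracle equivalence, encoding."""

from __future__ import annotations

from itertools import product
from pathlib import Path

import pytest

from _mrgn_oracle import GROUP_ORDER, LONG, grid_lines, oracle_category
from microfhir import codes, systems
from microfhir.errors import CannotEncodeError
from microfhir.mrgn import GROUPS, MRGNInput, classify, to_observation
from microfhir.terminology import ConceptRef

E_COLI = ConceptRef(system=systems.SNOMED, code=codes.E_COLI)
P_AERUGINOSA = ConceptRef(system=systems.SNOMED, code=codes.P_AERUGINOSA)


def panel(**overrides) -> dict[str, str]:
    base = {g: "S" for g in GROUPS}
    base.update(overrides)
    return base


def run(species=E_COLI, carb=False, neo=False, **overrides):
    return classify(
        MRGNInput(
            species=species,
            class_results=panel(**overrides),
            carbapenemase_detected=carb,
            neonatology=neo,
        )
    )


class TestRuleSentences:
    def test_carbapenemase_forces_4mrgn_regardless_of_phenotype(self):
        result = run(carb=True)  # all groups susceptible
        assert result.category == "4MRGN"
        assert result.rationale[0] == "carbapenemase-detected-4mrgn"

    def test_carbapenem_resistance_alone_is_4mrgn_for_non_pa(self):
        assert run(carbapenems="R").category == "4MRGN"

    def test_pa_is_exempt_from_the_carbapenem_rule(self):
        result = run(species=P_AERUGINOSA, carbapenems="R")
        assert result.category == "none"  # n = 1 resistant group
        assert "carbapenem-resistance-pa-exception" in result.rationale

    def test_pa_subtype_inherits_the_exception(self):
        subtype = ConceptRef(system=systems.SNOMED, code="990000301")
        assert run(species=subtype, carbapenems="R").category == "none"

    def test_three_of_four_resistant_is_3mrgn(self):
        result = run(ureidopenicillins="R", cephalosporins_3_4="R", fluoroquinolones="R")
        assert result.category == "3MRGN"

    def test_two_of_four_is_2mrgn_only_in_neonatology(self):
        two_r = dict(ureidopenicillins="R", cephalosporins_3_4="R")
        assert run(neo=True, **two_r).category == "2MRGN"
        assert run(neo=False, **two_r).category == "none"

    def test_intermediate_does_not_count_as_resistant_by_default(self):
        result = run(ureidopenicillins="R", cephalosporins_3_4="R", fluoroquinolones="I")
        assert result.category == "none"

    def test_strict_flag_counts_intermediate(self):
        inp = MRGNInput(
            species=E_COLI,
            class_results=panel(
                ureidopenicillins="R", cephalosporins_3_4="R", fluoroquinolones="I"
            ),
        )
        assert classify(inp, count_intermediate_as_resistant=True).category == "3MRGN"

    def test_untested_group_attaches_a_warning(self):
        result = run(ureidopenicillins="not-tested")
        assert any("not tested" in w for w in result.warnings)

    def test_non_gram_negative_species_warns_but_still_classifies(self):
        s_aureus = ConceptRef(system=systems.SNOMED, code="3092008")
        result = run(species=s_aureus, carb=True)
        assert result.category == "4MRGN"
        assert any("Gram-negative" in w for w in result.warnings)

    def test_missing_group_is_a_precondition_error(self):
        with pytest.raises(ValueError, match="four groups"):
            MRGNInput(species=E_COLI, class_results={"carbapenems": "R"})


class TestExhaustiveGrid:
    def test_matches_brute_force_oracle_everywhere(self):
        """All {S,I,R,not-tested}^4 x flags x species classes vs the oracle."""
        for results in product(("S", "I", "R", "not-tested"), repeat=4):
            class_results = dict(zip(GROUP_ORDER, results))
            for carb, neo, pa in product((False, True), repeat=3):
                species = P_AERUGINOSA if pa else E_COLI
                got = classify(
                    MRGNInput(
                        species=species,
                        class_results=class_results,
                        carbapenemase_detected=carb,
                        neonatology=neo,
                    )
                ).category
                expected = oracle_category(class_results, carb, neo, pa)
                assert got == expected, (results, carb, neo, pa)

    def test_monotonicity_s_to_r_never_lowers_the_category(self):
        rank = {"none": 0, "2MRGN": 2, "3MRGN": 3, "4MRGN": 4}
        for results in product(("S", "R"), repeat=4):
            class_results = dict(zip(GROUP_ORDER, results))
            for neo, pa in product((False, True), repeat=2):
                species = P_AERUGINOSA if pa else E_COLI
                base = classify(
                    MRGNInput(species=species, class_results=class_results,
                              neonatology=neo)
                ).category
                for group in GROUP_ORDER:
                    if class_results[group] == "R":
                        continue
                    raised = dict(class_results, **{group: "R"})
                    upgraded = classify(
                        MRGNInput(species=species, class_results=raised, neonatology=neo)
                    ).category
                    assert rank[upgraded] >= rank[base]

    def test_carbapenemase_dominates_every_input(self):
        for results in product(("S", "I", "R", "not-tested"), repeat=4):
            for neo, pa in product((False, True), repeat=2):
                species = P_AERUGINOSA if pa else E_COLI
                got = classify(
                    MRGNInput(
                        species=species,
                        class_results=dict(zip(GROUP_ORDER, results)),
                        carbapenemase_detected=True,
                        neonatology=neo,
                    )
                ).category
                assert got == "4MRGN"


class TestTruthTableRegression:
    def test_frozen_fixture_matches_current_behaviour(self):
        fixture = Path(__file__).parent / "data" / "mrgn_truth_table.csv"
        lines = fixture.read_text().splitlines()
        assert lines == grid_lines()  # fixture was generated by the oracle
        for line in lines[1:]:
            key, carb, neo, pa, expected = line.split(",")
            class_results = {
                g: LONG[ch] for g, ch in zip(GROUP_ORDER, key)
            }
            got = classify(
                MRGNInput(
                    species=P_AERUGINOSA if pa == "1" else E_COLI,
                    class_results=class_results,
                    carbapenemase_detected=carb == "1",
                    neonatology=neo == "1",
                )
            ).category
            assert got == expected, line


class TestEncoding:
    @pytest.mark.parametrize(
        "category,answer",
        [("2MRGN", "LA33214-0"), ("3MRGN", "LA33215-7"), ("4MRGN", "LA33216-5")],
    )
    def test_answer_codes_match_categories(self, category, answer):
        if category == "4MRGN":
            result = run(carb=True)
        elif category == "3MRGN":
            result = run(ureidopenicillins="R", cephalosporins_3_4="R",
                         fluoroquinolones="R")
        else:
            result = run(neo=True, ureidopenicillins="R", cephalosporins_3_4="R")
        assert result.category == category
        obs = to_observation(result, id="iso-1")
        assert obs.value.code == answer
        assert obs.kind == "mrgn_class"

    def test_category_none_cannot_be_encoded(self):
        with pytest.raises(CannotEncodeError):
            to_observation(run(), id="iso-1")
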