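"""KRINKO MRGN classification of Gram-negative isolates.

An isolate is rated against four antibiotic groups — ureidopenicillins,
3rd/4th-generation cephalosporins, carbapenems and fluoroquinolones.  The
category 2MRGN / 3MRGN / 4MRGN states resistance against 2, 3 or 4 of the
four groups, with two overriding rules: a detected carbapenemase always
means 4MRGN irrespective of phenotypic testing, and carbapenem resistance
alone means 4MRGN except for *Pseudomonas aeruginosa*.  2MRGN is used only
in neonatology.

Only "R" counts as resistant for the group count by default; "I"
(intermediate / susceptible-increased exposure) can be counted as resistant
via ``count_intermediate_as_resistant`` since local practice varies.
Untested groups count as not resistant, with a warning, because
under-testing can under-classify.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import codes, systems
from .context import active_context
from .errors import CannotEncodeError
from .terminology import ConceptRef, SnapshotRegistry, ancestors

__all__ = ["GROUPS", "GroupResult", "MRGNInput", "MRGNResult", "classify", "to_observation"]

#: The four antibiotic groups, in canonical order.
GROUPS = ("ureidopenicillins", "cephalosporins_3_4", "carbapenems", "fluoroquinolones")

GroupResult = Literal["S", "I", "R", "not-tested"]


class MRGNInput(BaseModel):
    """Susceptibility pattern and context of one Gram-negative isolate."""

    model_config = ConfigDict(frozen=True)

    species: ConceptRef
    class_results: dict[str, GroupResult]
    carbapenemase_detected: bool = False
    neonatology: bool = False

    @model_validator(mode="after")
    def _all_groups_present(self) -> "MRGNInput":
        if set(self.class_results) != set(GROUPS):
            missing = sorted(set(GROUPS) - set(self.class_results))
            extra = sorted(set(self.class_results) - set(GROUPS))
            raise ValueError(
                f"class_results must cover exactly the four groups "
                f"(missing {missing}, unexpected {extra})"
            )
        return self


class MRGNResult(BaseModel):
    """Classification outcome with the fired rules, in order."""

    model_config = ConfigDict(frozen=True)

    category: Literal["2MRGN", "3MRGN", "4MRGN", "none"]
    answer_code: Optional[ConceptRef] = None
    rationale: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _answer_matches_category(self) -> "MRGNResult":
        if (self.category == "none") != (self.answer_code is None):
            raise ValueError("answer_code present iff category != none")
        if self.category != "none" and self.answer_code != codes.MRGN_ANSWERS[self.category]:
            raise ValueError("answer_code must match the category")
        return self


def _is_p_aeruginosa(species: ConceptRef, registry: SnapshotRegistry) -> tuple[bool, bool]:
    """(is P. aeruginosa or a subtype, species known to the snapshot)."""
    if species.system != systems.SNOMED:
        return False, False
    snap = registry.get(systems.SNOMED)
    if species.code not in snap:
        return False, False
    if species.code == codes.P_AERUGINOSA:
        return True, True
    return codes.P_AERUGINOSA in ancestors(snap, species.code), True


def classify(
    input: MRGNInput,
    registry: Optional[SnapshotRegistry] = None,
    *,
    count_intermediate_as_resistant: bool = False,
) -> MRGNResult:
    """Apply the MRGN rules in order and return category + rationale."""
    registry = registry if registry is not None else active_context().registry
    rationale: list[str] = []
    warnings: list[str] = []

    pa, species_known = _is_p_aeruginosa(input.species, registry)
    if species_known:
        snap = registry.get(systems.SNOMED)
        lineage = ancestors(snap, input.species.code) | {input.species.code}
        if codes.GRAM_NEGATIVE_ROOT not in lineage:
            warnings.append(
                f"species {input.species.code} is not in the Gram-negative fixture set; "
                "MRGN is defined for Gram-negative organisms"
            )
    else:
        warnings.append(
            f"species {input.species.code} is unknown to the active snapshot; "
            "treated as non-P.-aeruginosa Gram-negative"
        )
    untested = [g for g in GROUPS if input.class_results[g] == "not-tested"]
    if untested:
        warnings.append(
            f"groups not tested: {', '.join(untested)}; the category may under-classify"
        )

    def done(category: str) -> MRGNResult:
        answer = codes.MRGN_ANSWERS[category] if category != "none" else None
        return MRGNResult(
            category=category,  # type: ignore[arg-type]
            answer_code=answer,
            rationale=tuple(rationale),
            warnings=tuple(warnings),
        )

    # rule 1: carbapenemase overrides everything
    if input.carbapenemase_detected:
        rationale.append("carbapenemase-detected-4mrgn")
        return done("4MRGN")

    # rule 2: carbapenem resistance, except P. aeruginosa
    if input.class_results["carbapenems"] == "R" and not pa:
        rationale.append("carbapenem-resistant-non-pa-4mrgn")
        return done("4MRGN")
    if input.class_results["carbapenems"] == "R" and pa:
        rationale.append("carbapenem-resistance-pa-exception")

    # rule 3: count resistant groups
    resistant = {"R", "I"} if count_intermediate_as_resistant else {"R"}
    n = sum(1 for g in GROUPS if input.class_results[g] in resistant)
    if n == 4:
        rationale.append("four-groups-resistant-4mrgn")
        return done("4MRGN")
    if n == 3:
        rationale.append("three-groups-resistant-3mrgn")
        return done("3MRGN")
    if n == 2:
        if input.neonatology:
            rationale.append("two-groups-resistant-neonatology-2mrgn")
            return done("2MRGN")
        rationale.append("two-groups-resistant-but-2mrgn-restricted-to-neonatology")
        return done("none")
    rationale.append("fewer-than-two-groups-resistant")
    return done("none")


def to_observation(result: MRGNResult, id: str = "mrgn-classification"):
    """Encode a classification as an MRGN observation (code 99780-9)."""
    if result.category == "none":
        raise CannotEncodeError("MRGN category 'none' has no answer code to encode")
    from .model import MRGNClassification

    return MRGNClassification(id=id, value=result.answer_code)
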