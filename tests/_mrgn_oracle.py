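"""Brute-force MRGN oracle: a direct transcription of the classification
rule sentences, independent of the package's rule engine.

Used both for the exhaustive-grid equivalence test and to (re)generate the
frozen truth-table regression fixture.
"""

from __future__ import annotations

from itertools import product

RESULTS = ("S", "I", "R", "not-tested")
SHORT = {"S": "S", "I": "I", "R": "R", "not-tested": "U"}
LONG = {v: k for k, v in SHORT.items()}
GROUP_ORDER = ("ureidopenicillins", "cephalosporins_3_4", "carbapenems", "fluoroquinolones")


def oracle_category(
    panel: dict[str, str], carbapenemase: bool, neonatology: bool, is_p_aeruginosa: bool
) -> str:
    """Sentence-by-sentence restatement of the MRGN rules."""
    # carbapenemase detection always means 4MRGN
    if carbapenemase:
        return "4MRGN"
    # carbapenem resistance means 4MRGN, except for P. aeruginosa
    if panel["carbapenems"] == "R" and not is_p_aeruginosa:
        return "4MRGN"
    # resistant towards 2, 3 or 4 of the 4 groups; 2MRGN only in neonatology
    n = sum(1 for g in GROUP_ORDER if panel[g] == "R")
    if n == 4:
        return "4MRGN"
    if n == 3:
        return "3MRGN"
    if n == 2 and neonatology:
        return "2MRGN"
    return "none"


def full_grid():
    """Every combination: 4 results per group x 2 flags x 2 species classes."""
    for results in product(RESULTS, repeat=4):
        panel = dict(zip(GROUP_ORDER, results))
        for carb, neo, pa in product((False, True), repeat=3):
            yield panel, carb, neo, pa


def grid_lines() -> list[str]:
    """Compact CSV lines: panel (SIRU letters), flags, expected category."""
    lines = ["panel,carbapenemase,neonatology,p_aeruginosa,category"]
    for panel, carb, neo, pa in full_grid():
        key = "".join(SHORT[panel[g]] for g in GROUP_ORDER)
        cat = oracle_category(panel, carb, neo, pa)
        lines.append(f"{key},{int(carb)},{int(neo)},{int(pa)},{cat}")
    return lines
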