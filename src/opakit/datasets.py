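"""Bundled reference tables from the 41-line DGRP opa survey.

These are the printed inputs of the survey this package models: per-group
line genotype lists, fecundity counts, the clone compositions of the four
genotyping quality-control (QC) experiments, and the observed Hardy-Weinberg
genotype counts.  They let the summary statistics and error-rate estimates
be recomputed from scratch without any external download.

The QC clone sets are reconstructed per individual from the printed class
totals.  Two printed tallies are internally inconsistent and are resolved in
favour of the printed totals and percentages: the somatic-variation
experiment enumerates 12 variant clones but reports 205/218 original (94.0%)
and 6.0% variants, which requires 13; and the interculture experiment's
"340 total clones" after removing 13 contaminants from 358 must be 345
(= 333 original + 12 contractions, matching the printed 96.5%/3.5%).
"""

from __future__ import annotations

from typing import Iterable

from .alleles import AlleleRecord, AlleleRegistry, CodonString, PqConfig, default_codon_string, default_registry
from .genotyping import CloneRecord
from .popqc import LineGenotype

# ---------------------------------------------------------------------------
# Line genotype lists per survey group.  "a/b" marks segregating lines.

SURVEY_GROUPS: dict[str, tuple[tuple[str, str], ...]] = {
    "notch_dirty_dozen": (
        ("21", "opa31"), ("237", "opa35a1"), ("350", "opa31"), ("439", "opa31"),
        ("440", "opa31"), ("555", "opa33a"), ("646", "opa23"), ("776", "opa33a"),
        ("796", "opa33a"), ("801", "opa32"), ("802", "opa32"), ("822", "opa31"),
    ),
    "radiation_resistant": (
        ("91", "opa31"), ("69", "opa32"), ("338", "opa32"), ("208", "opa31"),
        ("57", "opa33b"), ("492", "opa31"), ("142", "opa31/opa32"), ("879", "opa31"),
        ("370", "opa36/opa37"), ("808", "opa31"), ("237", "opa35a1"), ("88", "opa37"),
        ("405", "opa31"), ("646", "opa23"), ("801", "opa32"), ("105", "opa33b"),
        ("776", "opa33a"), ("195", "opa31"),
    ),
    "radiation_sensitive": (
        ("21", "opa31"), ("350", "opa31"), ("365", "opa31"), ("439", "opa31"),
        ("440", "opa31"), ("555", "opa33a"), ("712", "opa31"), ("796", "opa33a"),
        ("802", "opa32"), ("820", "opa34"), ("822", "opa31"), ("832", "opa31"),
        ("837", "opa31"), ("852", "opa35a2"), ("859", "opa32"), ("861", "opa32"),
        ("882", "opa31"), ("887", "opa31"), ("890", "opa31"), ("897", "opa31"),
        ("908", "opa31"), ("911", "opa31"),
    ),
    "in3rk_homozygous": (
        ("100", "opa32"), ("105", "opa33b"), ("646", "opa23"),
    ),
}


def survey_line_genotypes(group: str) -> list[LineGenotype]:
    """The printed line genotypes of one survey group as LineGenotype records."""
    return [
        LineGenotype(line_id=line, haplotypes=tuple(geno.split("/")))
        for line, geno in SURVEY_GROUPS[group]
    ]


# Per-line fecundity (eggs laid in a 28-hr period at 25 degrees).
SURVEY_FECUNDITY: dict[str, int] = {
    "646": 1436, "021": 1196, "439": 1699, "440": 742, "822": 1438, "237": 2276,
}

# Observed RAL-142 genotype counts against the Hardy-Weinberg expectation
# (39 individuals; 144:124 females:males in the stock).
SEGREGATING_STOCK_OBSERVED = {"A_only": 13, "B_only": 14, "het_female": 12}
SEGREGATING_STOCK_SEX_COUNTS = (144, 124)  # females, males


# ---------------------------------------------------------------------------
# QC clone-set reconstructions


def _slip(registry: AlleleRegistry, parent: str, side: str, delta: int) -> CodonString:
    """Codon string for a slippage derivative of a registry allele.

    ``delta`` < 0 contracts, > 0 expands, on the given side of the histidine
    (histidine-less parents contract in their reference-left run).
    """
    cfg = registry[parent].config
    if not cfg.has_his:
        new = PqConfig(cfg.left_q + delta, False, 0)
    elif side == "L":
        new = PqConfig(cfg.left_q + delta, True, cfg.right_q)
    else:
        new = PqConfig(cfg.left_q, True, cfg.right_q + delta)
    return default_codon_string(new)


def _clones(line: str, individual: str, start: int, alleles: Iterable) -> list[CloneRecord]:
    return [
        CloneRecord(clone_id=f"{line}.{individual}.c{start + i}", line_id=line,
                    individual_id=individual, allele=allele)
        for i, allele in enumerate(alleles)
    ]


def pcr_control_clones(registry: AlleleRegistry | None = None) -> list[CloneRecord]:
    """PCR-error control: 21 clones off one opa31 template, one opa30L contraction."""
    reg = registry or default_registry()
    opa31 = reg["opa31"]
    opa30L = _slip(reg, "opa31", "L", -1)
    return _clones("PCRctl", "i1", 0, [opa31] * 20 + [opa30L])


def somatic_control_clones(registry: AlleleRegistry | None = None) -> list[CloneRecord]:
    """Somatic-variation control: 218 endogenous clones from one opa31 stock.

    205 original, 13 contraction clones (opa30L, opa29L and opa30R types; the
    printed totals imply 13 variants although only 12 are enumerated).
    """
    reg = registry or default_registry()
    opa31 = reg["opa31"]
    variants = (
        [_slip(reg, "opa31", "L", -1)] * 10      # opa30L
        + [_slip(reg, "opa31", "L", -2)]         # opa29L
        + [_slip(reg, "opa31", "R", -1)] * 2     # opa30R
    )
    return _clones("stock26820", "i1", 0, [opa31] * 205 + variants)


def intraculture_control_clones(registry: AlleleRegistry | None = None) -> list[CloneRecord]:
    """Intraculture control: 360 clones from 39 individuals of a segregating line.

    13 opa31-only, 14 opa32-only and 12 heterozygous individuals; 337
    original clones, 21 contractions (10 opa30L, 10 opa31L, 1 opa28L) and one
    opa33L expansion variant (2 clones), each variant clone a minor clone of
    its individual.
    """
    reg = registry or default_registry()
    opa31, opa32 = reg["opa31"], reg["opa32"]
    opa30L = _slip(reg, "opa31", "L", -1)   # Q12HQ17, off opa31
    opa28L = _slip(reg, "opa31", "L", -3)   # Q10HQ17, off opa31
    opa31L = _slip(reg, "opa32", "L", -1)   # Q12HQ18, off opa32
    opa33L = _slip(reg, "opa32", "L", +1)   # Q14HQ18, off opa32

    clones: list[CloneRecord] = []

    def add(individual: str, majors: list, variant=None, n: int = 9) -> None:
        group = [majors[i % len(majors)] for i in range(n - (1 if variant is not None else 0))]
        if variant is not None:
            group.append(variant)
        clones.extend(_clones("RAL-142", individual, 0, group))

    # 13 opa31-only individuals: 10 with an opa30L minor, 1 with opa28L.
    for i in range(10):
        add(f"A{i+1:02d}", [opa31], opa30L, n=9)
    add("A11", [opa31], opa28L, n=9)
    add("A12", [opa31], None, n=10)
    add("A13", [opa31], None, n=10)
    # 14 opa32-only individuals: 10 with an opa31L minor, 2 with an opa33L minor.
    for i in range(10):
        add(f"B{i+1:02d}", [opa32], opa31L, n=9)
    add("B11", [opa32], opa33L, n=10)
    add("B12", [opa32], opa33L, n=10)
    add("B13", [opa32], None, n=10)
    add("B14", [opa32], None, n=10)
    # 12 heterozygous individuals, clean 5:4 or 5:5 tallies.
    for i in range(12):
        add(f"H{i+1:02d}", [opa31, opa32], None, n=9 if i < 9 else 10)
    assert len(clones) == 360
    return clones


def interculture_control_clones(registry: AlleleRegistry | None = None) -> tuple[list[CloneRecord], dict]:
    """Interculture control: 358 clones from 38 homozygous opa23 individuals.

    333 original, 12 opa22L contraction singletons, and 13 clones of the
    segregating line handled the same day (6 opa31 + 7 opa32) spread over 10
    individuals.  Returns the clone list and the foreign-allele map naming
    the known alleles of that other culture.
    """
    reg = registry or default_registry()
    opa23, opa31, opa32 = reg["opa23"], reg["opa31"], reg["opa32"]
    opa22L = _slip(reg, "opa23", "L", -1)

    clones: list[CloneRecord] = []

    def add(individual: str, extras: list, n_total: int) -> None:
        majors = [opa23] * (n_total - len(extras))
        clones.extend(_clones("RAL-646", individual, 0, majors + extras))

    # 12 individuals with an opa22L singleton (9 clones each).
    for i in range(12):
        add(f"i{i+1:02d}", [opa22L], 9)
    # 10 contaminated individuals: 3 carry two foreign clones, 7 carry one.
    add("i13", [opa31, opa31], 10)
    add("i14", [opa31, opa32], 10)
    add("i15", [opa32, opa32], 10)
    for i, foreign in enumerate([opa31, opa31, opa31, opa32, opa32, opa32, opa32]):
        add(f"i{16+i:02d}", [foreign], 10)
    # 16 clean individuals (9 or 10 clones).
    for i in range(16):
        add(f"i{23+i:02d}", [], 10 if i < 6 else 9)
    assert len(clones) == 358
    return clones, {"RAL-646": [opa31, opa32]}
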