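"""Tests for clone tallying, genotype calling and error-rate estimation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opakit.alleles import (
    AlleleRecord,
    PqConfig,
    default_codon_string,
    default_registry,
    is_slippage_derivative,
)
from opakit.datasets import pcr_control_clones, somatic_control_clones, intraculture_control_clones, interculture_control_clones
from opakit.errors import EmptyInputError, UndefinedRateError
from opakit.genotyping import (
    CloneClass,
    CloneRecord,
    ErrorRates,
    GenotypeParams,
    call_individual,
    call_line,
    call_study,
    estimate_error_rates,
    tally,
)

REG = default_registry()


def _rec(name: str, pq: str) -> AlleleRecord:
    cfg = PqConfig.from_string(pq)
    return AlleleRecord(name, cfg, default_codon_string(cfg))


# a small allele universe for constructed tallies
A31 = REG["opa31"]
A32 = REG["opa32"]
A30L = _rec("opa30L", "Q12HQ17")    # contraction derivative of opa31
A31L = _rec("opa31L", "Q12HQ18")    # contraction derivative of opa32 (not of opa31)
A23 = REG["opa23"]


def make_clones(spec, line="L", individual="i1"):
    """spec: list of (AlleleRecord, count) -> clone records."""
    clones = []
    k = 0
    for rec, n in spec:
        for _ in range(n):
            k += 1
            clones.append(CloneRecord(f"{individual}.c{k}", line, rec, individual))
    return clones


class TestTally:
    def test_counts_and_order(self):
        t = tally(make_clones([(A31, 8), (A30L, 1)]))
        assert list(t.counts.values()) == [8, 1]
        assert t.total == 9

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            tally([])

    def test_same_pq_different_codons_tallied_separately(self):
        cfg = PqConfig(13, True, 21)
        a1 = AlleleRecord("opa35a1", cfg, default_codon_string(cfg, 0))
        a2 = AlleleRecord("opa35a2", cfg, default_codon_string(cfg, 1))
        t = tally(make_clones([(a1, 3), (a2, 2)]))
        assert len(t.counts) == 2


class TestCallIndividual:
    def test_singleton_contraction_is_slippage(self):
        call = call_individual(make_clones([(A31, 8), (A30L, 1)]))
        assert call.zygosity == "single-allele"
        assert call.alleles[0][0] == A31.codons.compact
        assert call.allele_classes[A30L.codons.compact] is CloneClass.SLIPPAGE_CONTRACTION

    def test_heterozygote_with_slippage_minor(self):
        call = call_individual(make_clones([(A31, 5), (A32, 4), (A31L, 1)]))
        assert call.zygosity == "heterozygous"
        called = {k for k, _ in call.alleles}
        assert called == {A31.codons.compact, A32.codons.compact}
        # opa31L = Q12HQ18 is derivable from opa32, not from opa31
        assert call.allele_classes[A31L.codons.compact] is CloneClass.SLIPPAGE_CONTRACTION

    def test_known_foreign_minor_is_interculture_contaminant(self):
        call = call_individual(
            make_clones([(A23, 8), (A31, 1)]), foreign_alleles=[A31, A32]
        )
        assert call.zygosity == "single-allele"
        assert call.alleles[0][0] == A23.codons.compact
        assert call.allele_classes[A31.codons.compact] is CloneClass.CONTAMINANT_INTERCULTURE

    def test_supported_foreign_allele_still_contaminant(self):
        # two foreign clones of ten must not produce a heterozygous call
        call = call_individual(
            make_clones([(A23, 8), (A31, 2)]), foreign_alleles=[A31, A32]
        )
        assert call.zygosity == "single-allele"
        assert call.allele_classes[A31.codons.compact] is CloneClass.CONTAMINANT_INTERCULTURE

    def test_dominated_contraction_candidate_demoted(self):
        # 8:2 favours slippage off the dominant allele over heterozygosity
        call = call_individual(make_clones([(A31, 8), (A30L, 2)]))
        assert call.zygosity == "single-allele"
        assert call.allele_classes[A30L.codons.compact] is CloneClass.SLIPPAGE_CONTRACTION

    def test_balanced_alleles_stay_heterozygous(self):
        # opa31 is a contraction derivative of opa32, but 5:4 is no artifact tally
        call = call_individual(make_clones([(A32, 5), (A31, 4)]))
        assert call.zygosity == "heterozygous"

    def test_singleton_unknown_needs_eight_clones(self):
        few = call_individual(make_clones([(A31, 6), (A23, 1)]))
        assert few.allele_classes[A23.codons.compact] is CloneClass.AMBIGUOUS
        many = call_individual(make_clones([(A31, 8), (A23, 1)]))
        assert many.allele_classes[A23.codons.compact] is CloneClass.CONTAMINANT_INTRACULTURE

    def test_no_candidate_yields_ambiguous_call(self):
        call = call_individual(
            make_clones([(A31, 1), (A32, 1), (A23, 1)]),
        )
        assert call.zygosity == "ambiguous"
        assert call.alleles == ()
        assert call.warnings

    def test_below_min_clones_warns(self):
        call = call_individual(make_clones([(A31, 3)]))
        assert call.zygosity == "single-allele"
        assert any("weakly supported" in w for w in call.warnings)

    def test_order_invariance(self):
        clones = make_clones([(A31, 5), (A32, 4), (A30L, 1), (A23, 1)])
        ref = call_individual(clones, foreign_alleles=[A23])
        rng = random.Random(7)
        for _ in range(5):
            shuffled = clones[:]
            rng.shuffle(shuffled)
            call = call_individual(shuffled, foreign_alleles=[A23])
            assert call.alleles == ref.alleles
            assert call.allele_classes == ref.allele_classes

    def test_every_clone_gets_exactly_one_class(self):
        clones = make_clones([(A31, 6), (A32, 5), (A30L, 2), (A23, 1)])
        call = call_individual(clones, foreign_alleles=[A23])
        assert sorted(call.counts.values(), reverse=True) == [6, 5, 2, 1]
        assert len(call.clone_classes()) == len(clones)
        assert set(call.allele_classes) == set(call.counts)


class TestCallLine:
    def test_polymorphic_line(self):
        calls = (
            [call_individual(make_clones([(A31, 9)], individual=f"a{i}"), individual_id=f"a{i}") for i in range(13)]
            + [call_individual(make_clones([(A32, 9)], individual=f"b{i}"), individual_id=f"b{i}") for i in range(14)]
            + [call_individual(make_clones([(A31, 5), (A32, 4)], individual=f"h{i}"), individual_id=f"h{i}") for i in range(12)]
        )
        line = call_line(calls, line_id="RAL-142")
        assert set(line.haplotypes) == {A31.codons.compact, A32.codons.compact}
        assert line.het

    def test_fixed_line(self):
        calls = [
            call_individual(make_clones([(A23, 9)], individual=f"i{i}"), individual_id=f"i{i}")
            for i in range(5)
        ]
        line = call_line(calls, line_id="RAL-646")
        assert line.haplotypes == (A23.codons.compact,)
        assert not line.het

    def test_single_individual(self):
        call = call_individual(make_clones([(A31, 9)]))
        line = call_line([call])
        assert line.haplotypes == (A31.codons.compact,)


class TestErrorRates:
    def test_pcr_control_contraction_rate(self):
        _, _, rates = call_study(pcr_control_clones())
        assert rates.n_total == 21
        assert rates.percent("contraction") == 4.8

    def test_somatic_control_original_rate(self):
        _, _, rates = call_study(somatic_control_clones())
        assert rates.n_total == 218
        assert rates.percent("original") == 94.0
        assert rates.percent("contraction") == 6.0

    def test_intraculture_control_rates(self):
        _, lines, rates = call_study(intraculture_control_clones())
        assert rates.n_total == 360
        assert rates.percent("original") == 93.6
        assert rates.percent("contraction") == 5.8
        assert rates.percent("expansion") == 0.6
        assert lines["RAL-142"].het

    def test_interculture_control_rates(self):
        clones, foreign = interculture_control_clones()
        calls, lines, rates = call_study(clones, foreign_map=foreign)
        assert rates.n_total == 358
        assert rates.percent("interculture") == 3.6
        cleaned = rates.without_interculture()
        assert cleaned.n_total == 345
        assert cleaned.percent("original") == 96.5
        assert cleaned.percent("contraction") == 3.5
        assert all(
            call.zygosity == "single-allele"
            for by_ind in calls.values()
            for call in by_ind.values()
        )

    def test_no_variants_gives_zero_rates(self):
        rates = estimate_error_rates([CloneClass.ORIGINAL] * 100)
        assert rates.contraction_rate == 0.0
        assert rates.percent("original") == 100.0

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRateError):
            estimate_error_rates([])
        with pytest.raises(UndefinedRateError):
            _ = ErrorRates(n_total=0).contraction_rate


# ---------------------------------------------------------------------------
# Brute-force oracle: an independent, naive re-statement of the calling rules
# applied to small tallies, checked against call_individual.

ORACLE_UNIVERSE = [A31, A32, A30L, A23]


def oracle_call(counts, params, foreign_names):
    """Naive rule application on a {record: count} tally."""
    total = sum(counts.values())
    foreign = {r.name for r in ORACLE_UNIVERSE if r.name in foreign_names}

    def is_foreign(rec):
        return rec.name in foreign

    cands = [
        r
        for r in counts
        if counts[r] >= params.het_min_support
        and counts[r] / total >= params.het_min_fraction
        and not is_foreign(r)
    ]
    changed = True
    while changed:
        changed = False
        for r in sorted(cands, key=lambda r: (counts[r], r.codons.compact)):
            for other in cands:
                if other is r:
                    continue
                flag, _, _ = is_slippage_derivative(r, other)
                if not flag:
                    continue
                dom = (
                    params.contraction_dominance
                    if r.total_residues < other.total_residues
                    else params.expansion_dominance
                )
                if counts[other] >= dom * counts[r]:
                    cands.remove(r)
                    changed = True
                    break
            if changed:
                break
    classes = {}
    for r in counts:
        if r in cands:
            classes[r] = CloneClass.ORIGINAL
            continue
        parents = [
            c for c in cands if is_slippage_derivative(r, c)[0]
        ]
        if parents:
            parents.sort(key=lambda c: (-counts[c], c.codons.compact))
            classes[r] = (
                CloneClass.SLIPPAGE_CONTRACTION
                if r.total_residues < parents[0].total_residues
                else CloneClass.SLIPPAGE_EXPANSION
            )
        elif is_foreign(r):
            classes[r] = CloneClass.CONTAMINANT_INTERCULTURE
        elif counts[r] == 1 and total >= params.singleton_contaminant_min_clones:
            classes[r] = CloneClass.CONTAMINANT_INTRACULTURE
        else:
            classes[r] = CloneClass.AMBIGUOUS
    if len(cands) == 1:
        zyg = "single-allele"
    elif len(cands) == 2:
        zyg = "heterozygous"
    else:
        zyg = "ambiguous"
    return zyg, {r.codons.compact for r in cands}, {
        r.codons.compact: c for r, c in classes.items()
    }


@given(
    counts=st.lists(st.integers(min_value=0, max_value=6), min_size=4, max_size=4),
    foreign=st.sampled_from([(), ("opa23",), ("opa31", "opa32")]),
)
@settings(max_examples=300, deadline=None)
def test_call_individual_matches_bruteforce_oracle(counts, foreign):
    spec = [(rec, n) for rec, n in zip(ORACLE_UNIVERSE, counts) if n > 0]
    if not spec or sum(counts) > 13:
        return
    params = GenotypeParams(min_clones=1)
    tallied = {rec: n for rec, n in spec}
    clones = make_clones(spec)
    foreign_records = [r for r in ORACLE_UNIVERSE if r.name in foreign]
    call = call_individual(clones, params, foreign_records)
    zyg, cands, classes = oracle_call(tallied, params, foreign)
    assert call.zygosity == zyg
    assert {k for k, _ in call.alleles} == cands
    assert call.allele_classes == classes
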