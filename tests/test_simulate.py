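"""Tests for the synthetic clone-library and phenotype-table generators."""

import numpy as np
import pytest

from opakit.alleles import classify_codons, default_registry
from opakit.errors import SimConfigError
from opakit.genotyping import CloneClass
from opakit.phenotype import BristleCategory
from opakit.simulate import (
    DEFAULT_LEFT_FLANK,
    DEFAULT_RIGHT_FLANK,
    SimConfig,
    build_sequence,
    default_study_config,
    mutate_clone,
    simulate_bristles,
    simulate_embryo_assay,
    simulate_individual,
    simulate_study,
)

REG = default_registry()


class TestBuildSequence:
    def test_lengths_with_default_flanks(self):
        assert len(build_sequence(REG["opa31"])) == 3 * 31 + 20
        assert len(build_sequence(REG["opa23"])) == 3 * 23 + 20

    def test_allele_without_codons_rejected(self):
        from opakit.alleles import AlleleRecord, PqConfig

        bare = AlleleRecord("opa31", PqConfig(13, True, 17), None)
        with pytest.raises(ValueError):
            build_sequence(bare)


class TestMutateClone:
    def test_zero_rates_identity(self):
        rng = np.random.default_rng(0)
        for rec in REG:
            codons, cls = mutate_clone(rec, (0.0, 0.0), rng)
            assert codons == rec.codons
            assert cls is CloneClass.ORIGINAL

    def test_forced_contraction_hits_left_cag_run(self):
        # the default wild-type pattern has its longest CAG run left of the His
        rng = np.random.default_rng(0)
        codons, cls = mutate_clone(REG["opa31"], (1.0, 0.0), rng)
        assert cls is CloneClass.SLIPPAGE_CONTRACTION
        assert classify_codons(codons).pq_string == "Q12HQ17"  # opa30L

    def test_forced_expansion(self):
        rng = np.random.default_rng(0)
        codons, cls = mutate_clone(REG["opa32"], (0.0, 1.0), rng)
        assert cls is CloneClass.SLIPPAGE_EXPANSION
        assert classify_codons(codons).pq_string == "Q14HQ18"  # opa33L

    def test_seeded_reproducibility(self):
        out1 = mutate_clone(REG["opa31"], (0.5, 0.1), np.random.default_rng(42))
        out2 = mutate_clone(REG["opa31"], (0.5, 0.1), np.random.default_rng(42))
        assert out1 == out2


class TestSimulateIndividual:
    def cfg(self, **kw):
        base = dict(
            lines={"L": {"opa31": 1.0}},
            contraction_rate=0.0, expansion_rate=0.0,
            intraculture_rate=0.0, interculture_rate=0.0,
            interculture_pool=(),
        )
        base.update(kw)
        return SimConfig(**base)

    def test_homozygote_zero_rates(self):
        clones, truth = simulate_individual(
            [REG["opa31"]], 9, self.cfg(), [REG["opa31"]], [],
            np.random.default_rng(0), "L", "L.i1",
        )
        assert len(clones) == 9
        assert {c.key for c in clones} == {REG["opa31"].codons.compact}
        assert all(t["true_class"] == "original" for t in truth)

    def test_heterozygote_allele_ratio(self):
        clones, _ = simulate_individual(
            [REG["opa31"], REG["opa32"]], 10_000, self.cfg(),
            [REG["opa31"], REG["opa32"]], [], np.random.default_rng(1), "L", "L.i1",
        )
        n31 = sum(c.key == REG["opa31"].codons.compact for c in clones)
        se = np.sqrt(0.25 * 10_000)
        assert abs(n31 - 5000) < 3 * se

    def test_full_contamination_boundary(self):
        cfg = self.cfg(interculture_rate=1.0, interculture_pool=("opa23",))
        clones, truth = simulate_individual(
            [REG["opa31"]], 20, cfg, [REG["opa31"]], [REG["opa23"]],
            np.random.default_rng(0), "L", "L.i1",
        )
        assert {c.key for c in clones} == {REG["opa23"].codons.compact}
        assert all(t["true_class"] == "contaminant_interculture" for t in truth)

    def test_empty_pool_with_nonzero_rate_rejected(self):
        cfg = self.cfg(intraculture_rate=0.5)
        with pytest.raises(SimConfigError):
            simulate_individual(
                [REG["opa31"]], 5, cfg, [], [], np.random.default_rng(0), "L", "i",
            )


class TestSimulateStudy:
    def test_default_study_shape(self):
        study = simulate_study(default_study_config(seed=3))
        assert len(study.individual_truth) == 40
        assert set(study.sample_sheet.columns) == {
            "clone_id", "line_id", "individual_id", "sex"
        }
        n = study.sample_sheet.groupby("individual_id").size()
        assert n.between(5, 13).all()
        # every emitted clone appears exactly once in the truth table
        assert sorted(study.clone_truth.clone_id) == sorted(
            cid for cid, _ in study.sequences
        )
        assert study.clone_truth.clone_id.is_unique

    def test_identical_seeds_are_byte_identical(self, tmp_path):
        a = simulate_study(default_study_config(seed=11))
        b = simulate_study(default_study_config(seed=11))
        assert a.sequences == b.sequences
        assert a.clone_truth.equals(b.clone_truth)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        assert (tmp_path / "a" / "clones.fasta").read_bytes() == (
            tmp_path / "b" / "clones.fasta"
        ).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_study(default_study_config(seed=0))
        b = simulate_study(default_study_config(seed=1))
        assert a.sequences != b.sequences

    def test_males_are_hemizygous(self):
        cfg = SimConfig(
            lines={"L": {"opa31": 0.5, "opa32": 0.5}},
            individuals_per_line=40,
            interculture_rate=0.0, interculture_pool=(),
            seed=5,
        )
        study = simulate_study(cfg)
        males = study.individual_truth[study.individual_truth.sex == "M"]
        assert len(males) > 0
        assert (~males.alleles.str.contains("/")).all()

    def test_empty_study(self):
        cfg = SimConfig(lines={}, interculture_rate=0.0, interculture_pool=())
        study = simulate_study(cfg)
        assert study.sequences == []
        assert study.sample_sheet.empty

    def test_unknown_allele_rejected(self):
        cfg = SimConfig(
            lines={"L": {"opa99": 1.0}}, interculture_rate=0.0, interculture_pool=()
        )
        with pytest.raises(SimConfigError):
            simulate_study(cfg)

    def test_invalid_rates_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(lines={"L": {"opa31": 1.0}}, contraction_rate=1.5)


class TestSimulateBristles:
    def test_zero_probabilities_all_normal(self):
        table = simulate_bristles({}, 5, 0)
        assert (table.category == "normal").all()
        assert len(table) == 5 * 2 * 2 * 13  # flies x sexes x sides x positions

    def test_empirical_rate_matches_probability(self):
        table = simulate_bristles(
            {"pDC": {"ectopic_near": 0.1}}, 2500, 7, sexes=("F",)
        )
        at_pos = table[table.position == "pDC"]
        n = len(at_pos)  # 5000 hemi-nota
        rate = (at_pos.category == "ectopic_near").mean()
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(rate - 0.1) < 3 * se

    def test_seeded_reproducibility(self):
        a = simulate_bristles({"aSC": {"missing": 0.2}}, 20, 9)
        b = simulate_bristles({"aSC": {"missing": 0.2}}, 20, 9)
        assert a.equals(b)

    def test_bad_position_rejected(self):
        with pytest.raises(ValueError):
            simulate_bristles({"zZZ": {"missing": 0.1}}, 5, 0)


class TestSimulateEmbryoAssay:
    def test_boundaries(self):
        assert simulate_embryo_assay(0.0, 500, 0) == (0, 500)
        assert simulate_embryo_assay(1.0, 500, 0) == (500, 500)

    def test_empirical_rate(self):
        unhatched, total = simulate_embryo_assay(0.27, 10_000, 3)
        se = np.sqrt(0.27 * 0.73 / total)
        assert abs(unhatched / total - 0.27) < 3 * se
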