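"""End-to-end pipeline glue: simulated study -> extraction -> genotype calls.

Convenience layer for validation experiments: runs anchored extraction over
a simulated clone library, genotypes every individual (supplying each line's
known-foreign allele list, as the interculture QC experiment did), and
scores calling accuracy and error-rate recovery against the generator's
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .alleles import AlleleRegistry, CodonString, default_registry
from .extraction import AnchorConfig, locate_and_extract
from .genotyping import CloneRecord, ErrorRates, GenotypeCall, GenotypeParams, call_study
from .popqc import LineGenotype
from .simulate import StudyData


def extract_study_clones(study: StudyData) -> list[CloneRecord]:
    """Anchored extraction of every simulated clone sequence into clone records."""
    anchors = AnchorConfig(study.config.flank_left, study.config.flank_right)
    sheet = study.sample_sheet.set_index("clone_id")
    clones = []
    for clone_id, seq in study.sequences:
        locus = locate_and_extract(seq, anchors, sequence_id=clone_id)
        row = sheet.loc[clone_id]
        clones.append(
            CloneRecord(
                clone_id=clone_id,
                line_id=row["line_id"],
                individual_id=row["individual_id"],
                allele=CodonString(locus.codons.codons),
            )
        )
    return clones


def study_foreign_map(study: StudyData, registry: Optional[AlleleRegistry] = None) -> dict:
    """Per line, the alleles known to belong to other cultures in the study."""
    registry = registry or default_registry()
    line_alleles = {lid: set(spec) for lid, spec in study.config.lines.items()}
    pool = set(study.config.interculture_pool)
    out = {}
    for lid in line_alleles:
        others = pool.union(*(v for k, v in line_alleles.items() if k != lid))
        out[lid] = [registry[name] for name in others - line_alleles[lid]]
    return out


@dataclass
class RecoveryResult:
    """Pipeline-recovery scorecard against a simulated study's ground truth."""

    n_individuals: int
    n_correct: int
    rates: ErrorRates
    calls: dict[str, dict[str, GenotypeCall]]
    line_genotypes: dict[str, LineGenotype]

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_individuals


def evaluate_recovery(
    study: StudyData,
    params: Optional[GenotypeParams] = None,
    registry: Optional[AlleleRegistry] = None,
) -> RecoveryResult:
    """Extract, genotype and score a simulated study against its truth."""
    registry = registry or default_registry()
    clones = extract_study_clones(study)
    calls, lines, rates = call_study(clones, params, study_foreign_map(study, registry))
    compact_to_name = {
        rec.codons.compact: rec.name for rec in registry if rec.codons is not None
    }
    truth = {
        row.individual_id: set(row.alleles.split("/"))
        for row in study.individual_truth.itertuples()
    }
    n_correct = n_total = 0
    for by_ind in calls.values():
        for ind, call in by_ind.items():
            called = {compact_to_name.get(key, key) for key, _ in call.alleles}
            n_total += 1
            n_correct += called == truth[ind]
    return RecoveryResult(
        n_individuals=n_total,
        n_correct=n_correct,
        rates=rates,
        calls=calls,
        line_genotypes=lines,
    )
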