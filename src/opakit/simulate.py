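"""Synthetic Sanger clone libraries and phenotype tables with ground truth.

The generator emulates the study design the genotyping pipeline assumes: a
panel of inbred lines genotyped by sequencing 5-13 plasmid clones from each
of several individuals per line, with PCR slippage contracting (default
5%/clone) or expanding (0.6%/clone) the repeat, and environmental
contamination replacing a clone with a bottle mate's allele (intraculture,
5.7%) or another stock's allele (interculture, 3.6%).  X-linkage is
respected: males are hemizygous and carry one allele.  Every emitted clone
carries a ground-truth class and source allele, so calling accuracy and
error-rate recovery are directly measurable.

One global seed governs all draws through a fixed stream-splitting order
(lines, then individuals, then clones), so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alleles import (
    AlleleRecord,
    AlleleRegistry,
    CodonString,
    classify_codons,
    default_registry,
    _gln_runs,
)
from .errors import SimConfigError
from .genotyping import CloneClass, CloneRecord

#: Default synthetic flanks (the true genomic flanks are not bundled); both
#: satisfy the anchor invariants (no in-frame CAX run).
DEFAULT_LEFT_FLANK = "TGTCGGATTC"
DEFAULT_RIGHT_FLANK = "GATTCGGTGT"


@dataclass(frozen=True)
class SimConfig:
    """Study design for a simulated clone-sequencing experiment.

    ``lines`` maps line ids to allele-frequency dicts (one allele for a fixed
    line; two with frequencies for a segregating line).  Rates are per-clone
    probabilities.  ``interculture_pool`` names alleles carried by foreign
    stocks; the intraculture pool of a line is the line's own allele set
    (contamination comes from bottle mates).
    """

    lines: Mapping[str, Mapping[str, float]]
    individuals_per_line: int = 5
    fraction_female: float = 0.537
    clones_min: int = 5
    clones_max: int = 13
    contraction_rate: float = 0.05
    expansion_rate: float = 0.006
    intraculture_rate: float = 0.057
    interculture_rate: float = 0.036
    interculture_pool: tuple[str, ...] = ()
    flank_left: str = DEFAULT_LEFT_FLANK
    flank_right: str = DEFAULT_RIGHT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.contraction_rate, self.expansion_rate,
                 self.intraculture_rate, self.interculture_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise SimConfigError("rates must lie in [0, 1]")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise SimConfigError("fraction_female must lie in [0, 1]")
        if not 1 <= self.clones_min <= self.clones_max:
            raise SimConfigError("clone count range must satisfy 1 <= min <= max")
        if self.interculture_rate > 0 and not self.interculture_pool:
            raise SimConfigError("interculture contamination needs a non-empty pool")
        for line_id, freqs in self.lines.items():
            if not freqs or len(freqs) > 2:
                raise SimConfigError(f"line {line_id!r} must carry one or two alleles")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise SimConfigError(f"line {line_id!r} allele frequencies must sum to 1")


def default_study_config(seed: int = 0) -> SimConfig:
    """The default simulated panel: eight fixed lines of 5 individuals each
    (40 individuals), one registry allele per line, and the histidine-less
    opa23 as the foreign stock in the interculture pool (a foreign allele
    maximally distinct from the panel, never confusable with slippage)."""
    alleles = ["opa31", "opa32", "opa33a", "opa33b", "opa34", "opa35a1", "opa35a2", "opa36"]
    return SimConfig(
        lines={f"L{i+1:02d}": {a: 1.0} for i, a in enumerate(alleles)},
        interculture_pool=("opa23",),
        seed=seed,
    )


def build_sequence(allele: AlleleRecord, flanks: tuple[str, str] = (DEFAULT_LEFT_FLANK, DEFAULT_RIGHT_FLANK)) -> str:
    """Deterministic clone sequence: left flank + repeat codons + right flank."""
    if allele.codons is None:
        raise ValueError(f"allele {allele.name!r} has no codon string")
    return flanks[0] + allele.codons.dna + flanks[1]


def mutate_clone(
    allele: AlleleRecord,
    rates: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[CodonString, CloneClass]:
    """Apply per-clone PCR slippage: single-codon contraction or expansion.

    The event hits the longest run of identical glutamine codons (ties broken
    at random), matching the observed dominance of (CAG)7 -> (CAG)6 type
    contractions.  ``rates`` is (contraction, expansion).
    """
    if allele.codons is None:
        raise ValueError(f"allele {allele.name!r} has no codon string")
    contraction, expansion = rates
    u = rng.random()
    if u >= contraction + expansion:
        return allele.codons, CloneClass.ORIGINAL
    runs = _gln_runs(allele.codons)
    if not runs:
        return allele.codons, CloneClass.ORIGINAL
    longest = max(end - start for start, end, _ in runs)
    top = [r for r in runs if r[1] - r[0] == longest]
    start, end, codon = top[rng.integers(len(top))] if len(top) > 1 else top[0]
    cs = allele.codons.codons
    if u < contraction:
        return CodonString(cs[:end - 1] + cs[end:]), CloneClass.SLIPPAGE_CONTRACTION
    return CodonString(cs[:end] + (codon,) + cs[end:]), CloneClass.SLIPPAGE_EXPANSION


def simulate_individual(
    genotype: Sequence[AlleleRecord],
    n_clones: int,
    config: SimConfig,
    intra_pool: Sequence[AlleleRecord],
    inter_pool: Sequence[AlleleRecord],
    rng: np.random.Generator,
    line_id: str = "",
    individual_id: str = "",
) -> tuple[list[CloneRecord], list[dict]]:
    """Clones for one individual plus their ground-truth rows.

    Each clone picks one of the individual's alleles (50/50 for
    heterozygotes), passes through :func:`mutate_clone`, then may be replaced
    outright by a contaminant draw (interculture from the foreign pool,
    intraculture from the line's bottle mates).
    """
    if not 1 <= len(genotype) <= 2:
        raise SimConfigError("an individual carries one or two alleles")
    if config.intraculture_rate > 0 and not intra_pool:
        raise SimConfigError("intraculture contamination needs a non-empty pool")
    if config.interculture_rate > 0 and not inter_pool:
        raise SimConfigError("interculture contamination needs a non-empty pool")
    clones, truth = [], []
    for i in range(n_clones):
        source = genotype[rng.integers(len(genotype))] if len(genotype) > 1 else genotype[0]
        codons, cls = mutate_clone(source, (config.contraction_rate, config.expansion_rate), rng)
        u = rng.random()
        if u < config.interculture_rate:
            source = inter_pool[rng.integers(len(inter_pool))]
            codons, cls = source.codons, CloneClass.CONTAMINANT_INTERCULTURE
        elif u < config.interculture_rate + config.intraculture_rate:
            source = intra_pool[rng.integers(len(intra_pool))]
            codons, cls = source.codons, CloneClass.CONTAMINANT_INTRACULTURE
        clone_id = f"{individual_id}.c{i+1:02d}"
        clones.append(
            CloneRecord(clone_id=clone_id, line_id=line_id,
                        individual_id=individual_id, allele=codons)
        )
        truth.append(
            {
                "clone_id": clone_id,
                "line_id": line_id,
                "individual_id": individual_id,
                "true_class": cls.value,
                "source_allele": source.name,
                "third_position_string": codons.compact,
            }
        )
    return clones, truth


@dataclass
class StudyData:
    """A simulated study: sequences, sample sheet, and ground truth."""

    sequences: list[tuple[str, str]]           # (clone_id, nucleotide sequence)
    sample_sheet: pd.DataFrame                 # clone_id, line_id, individual_id, sex
    clone_truth: pd.DataFrame
    individual_truth: pd.DataFrame             # individual_id, line_id, sex, alleles
    config: SimConfig

    def write(self, outdir) -> None:
        """FASTA + sample sheet + truth TSVs + a config echo."""
        import yaml
        from pathlib import Path

        from .io import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "clones.fasta")
        self.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
        self.clone_truth.to_csv(outdir / "clone_truth.tsv", sep="\t", index=False)
        self.individual_truth.to_csv(outdir / "individual_truth.tsv", sep="\t", index=False)
        cfg = {
            k: (dict({kk: dict(vv) for kk, vv in v.items()}) if k == "lines" else
                list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.config).items()
        }
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def simulate_study(config: SimConfig, registry: Optional[AlleleRegistry] = None) -> StudyData:
    """Simulate a whole clone-sequencing study from a :class:`SimConfig`."""
    registry = registry or default_registry()
    for line_id, freqs in config.lines.items():
        for name in freqs:
            if name not in registry:
                raise SimConfigError(f"line {line_id!r} allele {name!r} not in registry")
    for name in config.interculture_pool:
        if name not in registry:
            raise SimConfigError(f"interculture allele {name!r} not in registry")

    inter_pool = [registry[n] for n in config.interculture_pool]
    root = np.random.SeedSequence(config.seed)
    line_seeds = root.spawn(len(config.lines))

    sequences: list[tuple[str, str]] = []
    sheet_rows, truth_rows, ind_rows = [], [], []
    for line_seed, (line_id, freqs) in zip(line_seeds, config.lines.items()):
        names = sorted(freqs)
        probs = np.array([freqs[n] for n in names])
        records = [registry[n] for n in names]
        intra_pool = records
        ind_seeds = line_seed.spawn(config.individuals_per_line)
        for j, ind_seed in enumerate(ind_seeds):
            rng = np.random.default_rng(ind_seed)
            individual_id = f"{line_id}.ind{j+1:02d}"
            sex = "F" if rng.random() < config.fraction_female else "M"
            n_draws = 2 if sex == "F" else 1
            genotype = [records[k] for k in rng.choice(len(records), size=n_draws, p=probs)]
            if sex == "F" and genotype[0].name == genotype[1].name:
                genotype = [genotype[0]]
            n_clones = int(rng.integers(config.clones_min, config.clones_max + 1))
            clones, truth = simulate_individual(
                genotype, n_clones, config, intra_pool, inter_pool, rng,
                line_id=line_id, individual_id=individual_id,
            )
            for clone in clones:
                seq = config.flank_left + clone.codons.dna + config.flank_right
                sequences.append((clone.clone_id, seq))
                sheet_rows.append(
                    {"clone_id": clone.clone_id, "line_id": line_id,
                     "individual_id": individual_id, "sex": sex}
                )
            truth_rows.extend(truth)
            ind_rows.append(
                {"individual_id": individual_id, "line_id": line_id, "sex": sex,
                 "alleles": "/".join(sorted(a.name for a in genotype))}
            )
    return StudyData(
        sequences=sequences,
        sample_sheet=pd.DataFrame(sheet_rows, columns=["clone_id", "line_id", "individual_id", "sex"]),
        clone_truth=pd.DataFrame(truth_rows, columns=["clone_id", "line_id", "individual_id",
                                                      "true_class", "source_allele",
                                                      "third_position_string"]),
        individual_truth=pd.DataFrame(ind_rows, columns=["individual_id", "line_id", "sex", "alleles"]),
        config=config,
    )


# ---------------------------------------------------------------------------
# Phenotype-table simulators


def simulate_bristles(
    defect_probs: Mapping[str, Mapping[str, float]],
    n_flies: int,
    rng: np.random.Generator | int,
    genotype: str = "",
    sexes: Sequence[str] = ("F", "M"),
) -> pd.DataFrame:
    """Categorical bristle observations for ``n_flies`` per sex, two hemi-nota each.

    ``defect_probs`` maps a bristle position to its per-hemi-notum defect
    category probabilities (e.g. ``{"pDC": {"ectopic_near": 0.1}}``); the
    remaining mass is NORMAL.  Unlisted positions are always NORMAL.
    """
    from .phenotype import BRISTLE_POSITIONS, BristleCategory

    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    for pos, cats in defect_probs.items():
        if pos not in BRISTLE_POSITIONS:
            raise ValueError(f"unknown bristle position {pos!r}")
        total = sum(cats.values())
        if any(p < 0 for p in cats.values()) or total > 1.0 + 1e-12:
            raise ValueError(f"defect probabilities at {pos!r} must sum to <= 1")
    rows = []
    for sex in sexes:
        for f in range(n_flies):
            fly_id = f"{genotype or 'sim'}.{sex}{f+1:04d}"
            for side in ("L", "R"):
                for pos in BRISTLE_POSITIONS:
                    cats = defect_probs.get(pos, {})
                    names = list(cats)
                    probs = [cats[c] for c in names]
                    u = rng.random()
                    acc = 0.0
                    category = BristleCategory.NORMAL.value
                    for name, p in zip(names, probs):
                        acc += p
                        if u < acc:
                            category = name if isinstance(name, str) else name.value
                            break
                    rows.append(
                        {"fly_id": fly_id, "sex": sex, "side": side,
                         "genotype": genotype, "position": pos, "category": category}
                    )
    return pd.DataFrame(rows)


def simulate_embryo_assay(
    p_fail: float, n_embryos: int, rng: np.random.Generator | int
) -> tuple[int, int]:
    """Binomial hatch assay: (unhatched, total)."""
    if not 0.0 <= p_fail <= 1.0:
        raise ValueError("p_fail must lie in [0, 1]")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return int(rng.binomial(n_embryos, p_fail)), n_embryos
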