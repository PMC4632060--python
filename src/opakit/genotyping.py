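"""Clone-library genotype calling with an explicit slippage/contamination model.

Sanger genotyping of a triplet repeat sequences several independent plasmid
clones per individual.  PCR replication slippage contracts (and rarely
expands) the repeat in a few percent of clones, and environmental
contamination can introduce clones from other individuals (intraculture) or
other stocks (interculture).  The caller tallies clone alleles per
individual, identifies the supported true allele(s), and assigns every minor
clone a class: slippage contraction/expansion, contaminant, or ambiguous.
Class counts across a study yield the empirical error-rate estimates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from ._util import percent
from .alleles import (
    AlleleRecord,
    AlleleRegistry,
    CodonString,
    PqConfig,
    classify_codons,
    is_slippage_derivative,
    resolve_name,
)
from .errors import EmptyInputError, UndefinedRateError
from .popqc import LineGenotype


class CloneClass(Enum):
    ORIGINAL = "original"
    SLIPPAGE_CONTRACTION = "slippage_contraction"
    SLIPPAGE_EXPANSION = "slippage_expansion"
    CONTAMINANT_INTRACULTURE = "contaminant_intraculture"
    CONTAMINANT_INTERCULTURE = "contaminant_interculture"
    AMBIGUOUS = "ambiguous"


@dataclass
class CloneRecord:
    """One sequenced clone: its origin and its repeat allele."""

    clone_id: str
    line_id: str
    allele: Union[AlleleRecord, CodonString]
    individual_id: Optional[str] = None
    clone_class: Optional[CloneClass] = None  # assigned by calling

    @property
    def codons(self) -> Optional[CodonString]:
        if isinstance(self.allele, CodonString):
            return self.allele
        return self.allele.codons

    @property
    def config(self) -> PqConfig:
        if isinstance(self.allele, CodonString):
            return classify_codons(self.allele)
        return self.allele.config

    @property
    def key(self) -> str:
        """Tally key: third-position string when codons are known, else pQ string."""
        codons = self.codons
        return codons.compact if codons is not None else self.config.pq_string


@dataclass(frozen=True)
class GenotypeParams:
    """Thresholds of the rule-based caller.

    ``het_min_support``/``het_min_fraction``: minimum clones (and clone
    fraction) for an allele to count as a true allele of the individual.
    ``singleton_contaminant_min_clones``: a singleton minor allele is called
    an intraculture contaminant only when at least this many clones were
    sequenced.  ``contraction_dominance``/``expansion_dominance``: a
    supported allele is demoted to a slippage artifact when it is a
    contraction (expansion) derivative of another candidate with at least
    this ratio more clones — true heterozygotes segregate near 1:1 while
    slippage minors sit near the per-clone error rate; expansion demands
    stronger dominance because it is the ~10x rarer artifact.
    """

    min_clones: int = 5
    het_min_support: int = 2
    het_min_fraction: float = 0.2
    singleton_contaminant_min_clones: int = 8
    max_del: int = 4
    max_ins: int = 2
    contraction_dominance: float = 2.0
    expansion_dominance: float = 3.0

    def __post_init__(self) -> None:
        if min(self.min_clones, self.het_min_support,
               self.singleton_contaminant_min_clones, self.max_del, self.max_ins) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.het_min_support < 1 or self.min_clones < 1:
            raise ValueError("support thresholds must be positive")


@dataclass
class GenotypeCall:
    """A per-individual call: zygosity, supported alleles, per-clone classes."""

    individual_id: str
    zygosity: str  # "single-allele" | "heterozygous" | "ambiguous"
    alleles: tuple[tuple[str, int], ...]        # called alleles with support
    allele_classes: dict[str, CloneClass]       # every tallied key -> class
    counts: dict[str, int]                      # every tallied key -> clones
    configs: dict[str, PqConfig]
    n_clones: int = 0
    warnings: tuple[str, ...] = ()

    def clone_classes(self) -> list[CloneClass]:
        """One class per clone (class counts partition the clone set)."""
        out = []
        for key, n in self.counts.items():
            out.extend([self.allele_classes[key]] * n)
        return out


class AlleleTally:
    """Clone counts per allele key, with per-key configuration and codons."""

    def __init__(self, clones: Sequence[CloneRecord]):
        if not clones:
            raise EmptyInputError("no clones to tally")
        counter: Counter[str] = Counter(c.key for c in clones)
        self.counts: dict[str, int] = dict(
            sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        self.configs: dict[str, PqConfig] = {}
        self.codons: dict[str, Optional[CodonString]] = {}
        for c in clones:
            self.configs.setdefault(c.key, c.config)
            self.codons.setdefault(c.key, c.codons)
        self.total = len(clones)

    def items(self):
        return self.counts.items()


def tally(clones: Sequence[CloneRecord]) -> AlleleTally:
    """Count clones per allele key (descending count, then key)."""
    return AlleleTally(clones)


def _foreign_matcher(foreign_alleles: Optional[Iterable]) -> "callable":
    """Build a predicate matching tallied keys against a known foreign set.

    Accepts allele records, configurations, pQ strings or third-position
    strings.  An entry whose codons are known matches at the nucleotide
    level only (two lines can carry the same pQ isoform with different codon
    histories); codon-less entries match on the pQ configuration.
    """
    pq: set[str] = set()
    compacts: set[str] = set()
    for item in foreign_alleles or ():
        if isinstance(item, AlleleRecord):
            if item.codons is not None:
                compacts.add(item.codons.compact)
            else:
                pq.add(item.pq_string)
        elif isinstance(item, PqConfig):
            pq.add(item.pq_string)
        elif isinstance(item, CodonString):
            compacts.add(item.compact)
        elif isinstance(item, str):
            if item.startswith("Q"):
                pq.add(item)
            else:
                compacts.add(item.upper())
        else:  # pragma: no cover
            raise TypeError(f"cannot interpret foreign allele {item!r}")

    def match(key: str, config: PqConfig) -> bool:
        return key in compacts or config.pq_string in pq

    return match


def call_individual(
    tallied: Union[AlleleTally, Sequence[CloneRecord]],
    params: Optional[GenotypeParams] = None,
    foreign_alleles: Optional[Iterable] = None,
    individual_id: str = "",
) -> GenotypeCall:
    """Call one individual's genotype from its clone tally.

    Candidate true alleles must reach ``het_min_support`` clones and
    ``het_min_fraction`` of the tally, and must not match the known foreign
    set.  A candidate that is a contraction derivative of a clearly dominant
    co-candidate is demoted to slippage.  Remaining minor alleles are
    classified as slippage derivatives of a candidate, known interculture
    contaminants, singleton intraculture contaminants (only when at least
    ``singleton_contaminant_min_clones`` clones were sequenced), or left
    ambiguous.  Zero surviving candidates yield an ambiguous call with a
    diagnostic rather than an exception.
    """
    params = params or GenotypeParams()
    if not isinstance(tallied, AlleleTally):
        tallied = AlleleTally(tallied)
    is_foreign = _foreign_matcher(foreign_alleles)
    warnings: list[str] = []
    if tallied.total < params.min_clones:
        warnings.append(
            f"only {tallied.total} clones (< {params.min_clones}); call is weakly supported"
        )

    keys = list(tallied.counts)
    candidates = [
        k
        for k in keys
        if tallied.counts[k] >= params.het_min_support
        and tallied.counts[k] / tallied.total >= params.het_min_fraction
        and not is_foreign(k, tallied.configs[k])
    ]

    # Demote supported alleles that look like slippage off a dominant candidate:
    # a slippage derivative of a co-candidate with >= dominance-fold support.
    demoted = True
    while demoted:
        demoted = False
        for k in sorted(candidates, key=lambda k: (tallied.counts[k], k)):
            for other in candidates:
                if other == k:
                    continue
                flag, _, _ = is_slippage_derivative(
                    tallied.configs[k], tallied.configs[other], params.max_del, params.max_ins
                )
                if not flag:
                    continue
                shrank = tallied.configs[k].total_residues < tallied.configs[other].total_residues
                dominance = params.contraction_dominance if shrank else params.expansion_dominance
                if tallied.counts[other] >= dominance * tallied.counts[k]:
                    candidates.remove(k)
                    demoted = True
                    break
            if demoted:
                break

    classes: dict[str, CloneClass] = {k: CloneClass.ORIGINAL for k in candidates}
    for k in keys:
        if k in classes:
            continue
        cfg = tallied.configs[k]
        parents = []
        for cand in candidates:
            flag, side, steps = is_slippage_derivative(
                cfg, tallied.configs[cand], params.max_del, params.max_ins
            )
            if flag:
                parents.append((tallied.counts[cand], cand, side, steps))
        if parents:
            # tie-break toward the higher-count parent, then alphabetically
            parents.sort(key=lambda t: (-t[0], t[1]))
            _, parent, side, steps = parents[0]
            shrank = cfg.total_residues < tallied.configs[parent].total_residues
            classes[k] = (
                CloneClass.SLIPPAGE_CONTRACTION if shrank else CloneClass.SLIPPAGE_EXPANSION
            )
        elif is_foreign(k, cfg):
            classes[k] = CloneClass.CONTAMINANT_INTERCULTURE
        elif tallied.counts[k] == 1 and tallied.total >= params.singleton_contaminant_min_clones:
            classes[k] = CloneClass.CONTAMINANT_INTRACULTURE
        else:
            classes[k] = CloneClass.AMBIGUOUS

    if len(candidates) == 1:
        zygosity = "single-allele"
    elif len(candidates) == 2:
        zygosity = "heterozygous"
    else:
        zygosity = "ambiguous"
        warnings.append(
            f"{len(candidates)} candidate alleles survive support thresholds"
        )

    return GenotypeCall(
        individual_id=individual_id,
        zygosity=zygosity,
        alleles=tuple((k, tallied.counts[k]) for k in candidates),
        allele_classes=classes,
        counts=dict(tallied.counts),
        configs=dict(tallied.configs),
        n_clones=tallied.total,
        warnings=tuple(warnings),
    )


def call_line(
    calls: Sequence[GenotypeCall], line_id: str = ""
) -> LineGenotype:
    """Aggregate individual calls into a line genotype.

    The line allele set is the union of called alleles across individuals; a
    line segregating two alleles is flagged heterozygous.  More than two
    segregating alleles is flagged (not fatal) and the two best-supported are
    kept.
    """
    if not calls:
        raise EmptyInputError("no individual calls")
    support: Counter[str] = Counter()
    for call in calls:
        for key, n in call.alleles:
            support[key] += n
    if not support:
        raise EmptyInputError("no supported alleles among individual calls")
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    flagged = ""
    if len(ranked) > 2:
        flagged = (
            f"{len(ranked)} alleles segregate; keeping the two best-supported"
        )
        ranked = ranked[:2]
    haplotypes = tuple(k for k, _ in ranked)
    return LineGenotype(line_id=line_id, haplotypes=haplotypes, flagged=flagged)


@dataclass(frozen=True)
class ErrorRates:
    """Class counts over a clone set; each rate is count / total clones."""

    n_total: int
    n_original: int = 0
    n_contraction: int = 0
    n_expansion: int = 0
    n_intraculture: int = 0
    n_interculture: int = 0
    n_ambiguous: int = 0

    def _rate(self, numerator: int) -> float:
        if self.n_total == 0:
            raise UndefinedRateError("no clones in denominator")
        return numerator / self.n_total

    @property
    def original_rate(self) -> float:
        return self._rate(self.n_original)

    @property
    def contraction_rate(self) -> float:
        return self._rate(self.n_contraction)

    @property
    def expansion_rate(self) -> float:
        return self._rate(self.n_expansion)

    @property
    def intraculture_rate(self) -> float:
        return self._rate(self.n_intraculture)

    @property
    def interculture_rate(self) -> float:
        return self._rate(self.n_interculture)

    def percent(self, which: str) -> float:
        """A rate as a one-decimal percent (half away from zero)."""
        return percent(getattr(self, f"n_{which}"), self.n_total)

    def without_interculture(self) -> "ErrorRates":
        """Rates recomputed after removing interculture contaminant clones."""
        return ErrorRates(
            n_total=self.n_total - self.n_interculture,
            n_original=self.n_original,
            n_contraction=self.n_contraction,
            n_expansion=self.n_expansion,
            n_intraculture=self.n_intraculture,
            n_interculture=0,
            n_ambiguous=self.n_ambiguous,
        )

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_original": self.n_original,
            "n_contraction": self.n_contraction,
            "n_expansion": self.n_expansion,
            "n_intraculture": self.n_intraculture,
            "n_interculture": self.n_interculture,
            "n_ambiguous": self.n_ambiguous,
            "original_pct": self.percent("original"),
            "contraction_pct": self.percent("contraction"),
            "expansion_pct": self.percent("expansion"),
            "intraculture_pct": self.percent("intraculture"),
            "interculture_pct": self.percent("interculture"),
        }


_CLASS_FIELD = {
    CloneClass.ORIGINAL: "n_original",
    CloneClass.SLIPPAGE_CONTRACTION: "n_contraction",
    CloneClass.SLIPPAGE_EXPANSION: "n_expansion",
    CloneClass.CONTAMINANT_INTRACULTURE: "n_intraculture",
    CloneClass.CONTAMINANT_INTERCULTURE: "n_interculture",
    CloneClass.AMBIGUOUS: "n_ambiguous",
}


def estimate_error_rates(classes: Iterable[CloneClass]) -> ErrorRates:
    """Empirical error rates from per-clone classifications."""
    counts = Counter(classes)
    if not counts:
        raise UndefinedRateError("no classified clones")
    kwargs = {field: 0 for field in _CLASS_FIELD.values()}
    for cls, n in counts.items():
        kwargs[_CLASS_FIELD[cls]] += n
    return ErrorRates(n_total=sum(counts.values()), **kwargs)


def call_study(
    clones: Sequence[CloneRecord],
    params: Optional[GenotypeParams] = None,
    foreign_map: Optional[Mapping[str, Iterable]] = None,
) -> tuple[dict[str, dict[str, GenotypeCall]], dict[str, LineGenotype], ErrorRates]:
    """Genotype a whole clone study grouped by line and individual.

    ``foreign_map`` optionally gives, per line, the alleles known to belong
    to *other* cultures (used to flag interculture contaminants).  Returns
    per-individual calls, per-line genotypes and pooled error rates.
    """
    params = params or GenotypeParams()
    by_line: dict[str, dict[str, list[CloneRecord]]] = {}
    for clone in clones:
        ind = clone.individual_id or clone.clone_id
        by_line.setdefault(clone.line_id, {}).setdefault(ind, []).append(clone)
    calls: dict[str, dict[str, GenotypeCall]] = {}
    line_genotypes: dict[str, LineGenotype] = {}
    all_classes: list[CloneClass] = []
    for line_id in sorted(by_line):
        foreign = (foreign_map or {}).get(line_id)
        calls[line_id] = {}
        for ind in sorted(by_line[line_id]):
            group = by_line[line_id][ind]
            call = call_individual(group, params, foreign, individual_id=ind)
            calls[line_id][ind] = call
            for clone in group:
                clone.clone_class = call.allele_classes[clone.key]
            all_classes.extend(call.clone_classes())
        line_genotypes[line_id] = call_line(
            list(calls[line_id].values()), line_id=line_id
        )
    return calls, line_genotypes, estimate_error_rates(all_classes)


def resolve_call_names(call: GenotypeCall, registry: AlleleRegistry) -> dict[str, str]:
    """Map each tallied key in a call to a registry allele name (minting as needed)."""
    names = {}
    for key in call.counts:
        codons = None if key.startswith("Q") else CodonString.from_thirds(key)
        cfg = call.configs[key]
        names[key] = resolve_name(cfg, codons, registry)
    return names
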