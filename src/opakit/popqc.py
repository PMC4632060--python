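"""Population summaries and X-linked Hardy-Weinberg expectations.

Line-level genotype summaries over a panel of inbred lines: the allele
distribution (heterozygous haplotypes weighted 0.5), the non-wild-type
fraction, the mean absolute deviation of repeat length from the wild-type 31
residues, and closed-form Hardy-Weinberg expected genotype counts at an
X-linked biallelic locus (males hemizygous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._util import round_half_away
from .alleles import parse_allele_name
from .errors import EmptyInputError


@dataclass(frozen=True)
class LineGenotype:
    """A line's called haplotypes: one for fixed lines, two for segregating."""

    line_id: str
    haplotypes: tuple[str, ...]
    flagged: str = ""  # non-fatal diagnostics (e.g. conflicting calls)

    def __post_init__(self) -> None:
        if not 1 <= len(self.haplotypes) <= 2:
            raise ValueError("a line carries one or two haplotypes")

    @property
    def het(self) -> bool:
        return len(set(self.haplotypes)) == 2


def allele_length(name: str) -> int:
    """Total residue count of a haplotype label.

    Accepts allele names (``opa33b`` -> 33, ``opa30L`` -> 30), pQ strings
    (``Q13HQ17`` -> 31) and third-position strings (length = residue count).
    """
    stripped = name[:-1] if name and name[-1] in "LR" and not set(name) <= set("ACGT") else name
    try:
        length, _, _, _ = parse_allele_name(stripped)
        return length
    except ValueError:
        pass
    if name.startswith("Q"):
        from .alleles import PqConfig

        return PqConfig.from_string(name).total_residues
    if name and set(name.upper()) <= set("ACGT"):
        return len(name)
    raise ValueError(f"cannot infer a repeat length from {name!r}")


def allele_distribution(lines: Sequence[LineGenotype]) -> dict[str, float]:
    """Allele name -> weight; homozygous lines count 1, het haplotypes 0.5 each.

    Ordered by total encoded length, then name; weights sum to the number of
    lines.
    """
    weights: dict[str, float] = {}
    for line in lines:
        if line.het:
            for h in line.haplotypes:
                weights[h] = weights.get(h, 0.0) + 0.5
        else:
            h = line.haplotypes[0]
            weights[h] = weights.get(h, 0.0) + 1.0
    return dict(sorted(weights.items(), key=lambda kv: (allele_length(kv[0]), kv[0])))


def nonwildtype_fraction(lines: Sequence[LineGenotype], wildtype: str = "opa31") -> float:
    """Fraction of haplotype weight carried by non-wild-type alleles."""
    if not lines:
        raise EmptyInputError("no lines")
    dist = allele_distribution(lines)
    total = sum(dist.values())
    return (total - dist.get(wildtype, 0.0)) / len(lines)


def mean_abs_deviation(lines: Sequence[LineGenotype], reference_length: int = 31) -> float:
    """Mean |repeat length - reference| per line, averaged over lines.

    A heterozygous line contributes the mean of its two haplotype deviations
    (each haplotype weighted 0.5).
    """
    if not lines:
        raise EmptyInputError("no lines")
    per_line = []
    for line in lines:
        devs = [abs(allele_length(h) - reference_length) for h in line.haplotypes]
        per_line.append(sum(devs) / len(devs))
    return sum(per_line) / len(per_line)


def sex_ratio(n_female: int, n_male: int) -> float:
    """Percent female, one decimal (half away from zero)."""
    if n_female + n_male == 0:
        raise EmptyInputError("no individuals")
    return round_half_away(100.0 * n_female / (n_female + n_male), 1)


@dataclass(frozen=True)
class HWExpectation:
    """X-linked Hardy-Weinberg expected genotype counts for two alleles A/B."""

    n: int
    n_female: int
    n_male: int
    p: float
    expected_raw: Mapping[str, float]      # {"A_only", "B_only", "het_female"}
    expected_rounded: Mapping[str, int]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.expected_raw)


def xlinked_hw_expected(n: int, percent_female: float, p: float) -> HWExpectation:
    """Expected X-linked genotype counts among ``n`` individuals.

    The female count is rounded to an integer before computing expectations
    (the only order consistent with counting whole flies); males are
    hemizygous so contribute ``M*p`` A-only individuals, females ``F*p^2``,
    and only females can be heterozygous (``F*2p(1-p)``).  Final expectations
    are also reported rounded half away from zero.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0.0 <= percent_female <= 100.0:
        raise ValueError("percent_female must lie in [0, 100]")
    n_female = int(round_half_away(n * percent_female / 100.0))
    n_male = n - n_female
    q = 1.0 - p
    raw = {
        "A_only": n_male * p + n_female * p * p,
        "B_only": n_male * q + n_female * q * q,
        "het_female": n_female * 2.0 * p * q,
    }
    rounded = {k: int(round_half_away(v)) for k, v in raw.items()}
    return HWExpectation(n, n_female, n_male, p, raw, rounded)


def goodness_of_fit(
    observed: Mapping[str, float], expected: Mapping[str, float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed vs expected counts: (statistic, df, p).

    Categories must match and expected counts must be positive.
    """
    if set(observed) != set(expected):
        raise ValueError("observed and expected categories differ")
    if any(e <= 0 for e in expected.values()):
        raise ValueError("expected counts must be positive")
    from scipy.stats import chi2

    stat = sum((observed[k] - expected[k]) ** 2 / expected[k] for k in expected)
    df = len(expected) - 1
    return stat, df, float(chi2.sf(stat, df))
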