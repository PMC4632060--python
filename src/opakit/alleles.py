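"""Polyglutamine (pQ) configurations, CAX codon strings and allele nomenclature.

The *opa* repeats of *Drosophila* *Notch* are a run of 5'-CAX codons encoding
two glutamine tracts separated by (at most) one histidine: Q_n H Q_m.  CAR
codons (CAA/CAG) encode glutamine; CAY codons (CAC/CAT) encode histidine.
Alleles are named by the total residue count (``opa31`` = Q13HQ17), with a
lowercase letter distinguishing same-length alleles whose histidine sits at a
different position (``opa33a`` = Q14HQ18 vs ``opa33b`` = Q15HQ17), a trailing
number distinguishing identical pQ isoforms encoded by different nucleotide
strings (``opa35a1``/``opa35a2``), and an opaque ``*n`` tag for synonymous
variants of a named allele.  Replication-slippage derivatives observed during
cloning are named ``opa{N}L`` / ``opa{N}R`` after the side of the histidine on
which the contraction or expansion occurred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .errors import EmptyInputError, MalformedRepeatError, RegistryIntegrityError

GLN_CODONS = frozenset({"CAA", "CAG"})
HIS_CODONS = frozenset({"CAC", "CAT"})
CAX_CODONS = GLN_CODONS | HIS_CODONS

#: Position of the histidine in the ancestral wild-type configuration
#: (Q13 H Q17): 13 glutamine codons precede it.  Used to assign an L/R side
#: label to slippage events in histidine-less alleles such as opa23.
REFERENCE_HIS_LEFT = 13

_NAME_RE = re.compile(r"^opa(\d+)([a-z]?)(\d*)$")


@dataclass(frozen=True, order=True)
class PqConfig:
    """A pQ tract layout: ``left_q`` glutamines, optional His, ``right_q`` more.

    An uninterrupted tract is stored entirely in ``left_q`` with
    ``has_his=False`` and ``right_q=0``.
    """

    left_q: int
    has_his: bool
    right_q: int = 0

    def __post_init__(self) -> None:
        if self.left_q < 0 or self.right_q < 0:
            raise ValueError("tract lengths must be non-negative")
        if not self.has_his and self.right_q != 0:
            raise ValueError("a histidine-less tract must have right_q == 0")

    @property
    def total_residues(self) -> int:
        return self.left_q + self.right_q + (1 if self.has_his else 0)

    @property
    def pq_string(self) -> str:
        if self.has_his:
            return f"Q{self.left_q}HQ{self.right_q}"
        return f"Q{self.left_q}"

    @classmethod
    def from_string(cls, s: str) -> "PqConfig":
        m = re.fullmatch(r"Q(\d+)(?:HQ(\d+))?", s)
        if m is None:
            raise ValueError(f"not a pQ string: {s!r}")
        left = int(m.group(1))
        if m.group(2) is None:
            return cls(left, False, 0)
        return cls(left, True, int(m.group(2)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pq_string


@dataclass(frozen=True)
class CodonString:
    """An ordered run of 5'-CAX codons (at most one histidine codon).

    The compact form is the string of third positions only (R bases A/G for
    glutamine, Y bases C/T for histidine); because every codon starts with CA,
    the third positions determine the codons completely.
    """

    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [c for c in self.codons if c not in CAX_CODONS]
        if bad:
            raise MalformedRepeatError(f"non-CAX codon(s): {bad}")
        if sum(c in HIS_CODONS for c in self.codons) > 1:
            raise MalformedRepeatError("more than one histidine codon")

    @classmethod
    def from_dna(cls, seq: str) -> "CodonString":
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise MalformedRepeatError("sequence length not divisible by 3")
        return cls(tuple(seq[i : i + 3] for i in range(0, len(seq), 3)))

    @classmethod
    def from_thirds(cls, thirds: str) -> "CodonString":
        return cls(tuple("CA" + b for b in thirds.upper()))

    @property
    def compact(self) -> str:
        return "".join(c[2] for c in self.codons)

    @property
    def dna(self) -> str:
        return "".join(self.codons)

    @property
    def his_index(self) -> Optional[int]:
        """0-based index of the histidine codon, or None."""
        for i, c in enumerate(self.codons):
            if c in HIS_CODONS:
                return i
        return None

    def __len__(self) -> int:
        return len(self.codons)

    def __iter__(self) -> Iterator[str]:
        return iter(self.codons)


def classify_codons(codons: CodonString | Iterable[str] | str) -> PqConfig:
    """Classify a CAX codon run into its Q_n[H]Q_m layout.

    Raises :class:`EmptyInputError` on empty input and
    :class:`MalformedRepeatError` for non-CAX codons or more than one
    histidine codon.
    """
    if isinstance(codons, str):
        codons = CodonString.from_dna(codons)
    elif not isinstance(codons, CodonString):
        codons = CodonString(tuple(codons))
    if len(codons) == 0:
        raise EmptyInputError("empty codon string")
    his = codons.his_index
    if his is None:
        return PqConfig(len(codons), False, 0)
    return PqConfig(his, True, len(codons) - his - 1)


def parse_allele_name(name: str) -> tuple[int, str, Optional[int], Optional[int]]:
    """Split an allele name into (length, letter, number, synonymous tag).

    ``opa35a2`` -> (35, 'a', 2, None); ``opa31*3`` -> (31, '', None, 3).
    """
    base, star, syn = name.partition("*")
    m = _NAME_RE.fullmatch(base)
    if m is None:
        raise ValueError(f"not an opa allele name: {name!r}")
    length = int(m.group(1))
    letter = m.group(2)
    number = int(m.group(3)) if m.group(3) else None
    return length, letter, number, (int(syn) if star else None)


@dataclass(frozen=True)
class AlleleRecord:
    """A registry entry: a name, its pQ configuration and (optionally) codons."""

    name: str
    config: PqConfig
    codons: Optional[CodonString] = None
    synonymous_suffix: Optional[int] = None
    derived_from: Optional[tuple[str, str]] = None  # (parent name, "L"/"R")
    notes: str = ""

    def __post_init__(self) -> None:
        length, _, _, _ = parse_allele_name(self.name.rstrip("LR") if self.name[-1] in "LR" and self.name[:-1][-1].isdigit() else self.name)
        if length != self.config.total_residues:
            raise ValueError(
                f"name {self.name!r} states length {length} but configuration "
                f"{self.config.pq_string} has {self.config.total_residues} residues"
            )
        if self.codons is not None:
            if len(self.codons) != self.config.total_residues:
                raise ValueError("codon string length disagrees with configuration")
            if classify_codons(self.codons) != self.config:
                raise ValueError("codon string does not encode the configuration")

    @property
    def total_residues(self) -> int:
        return self.config.total_residues

    @property
    def pq_string(self) -> str:
        return self.config.pq_string


def _parse_record_name(name: str) -> tuple[int, str]:
    """Length and side for slippage-style names; helper for validation."""
    if name[-1] in "LR":
        core = name[:-1]
        m = re.fullmatch(r"opa(\d+)", core)
        if m:
            return int(m.group(1)), name[-1]
    length, _, _, _ = parse_allele_name(name)
    return length, ""


class AlleleRegistry:
    """An ordered name -> :class:`AlleleRecord` mapping with naming policy.

    Letter suffixes are assigned in discovery (registration) order; numeric
    suffixes distinguish identical pQ isoforms with different codon strings.
    """

    def __init__(self, records: Iterable[AlleleRecord] = (), reference_his_left: int = REFERENCE_HIS_LEFT):
        self._records: dict[str, AlleleRecord] = {}
        self.reference_his_left = reference_his_left
        for rec in records:
            self.add(rec)

    def add(self, record: AlleleRecord) -> None:
        if record.name in self._records:
            raise RegistryIntegrityError(f"duplicate allele name {record.name!r}")
        self._records[record.name] = record

    def __getitem__(self, name: str) -> AlleleRecord:
        return self._records[name]

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __iter__(self) -> Iterator[AlleleRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def names(self) -> list[str]:
        return list(self._records)

    def by_length(self, total: int) -> list[AlleleRecord]:
        return [r for r in self if r.total_residues == total]

    def by_config(self, config: PqConfig) -> list[AlleleRecord]:
        return [r for r in self if r.config == config]

    def find_by_codons(self, codons: CodonString) -> Optional[AlleleRecord]:
        for r in self:
            if r.codons is not None and r.codons.codons == codons.codons:
                return r
        return None


def resolve_name(
    config: PqConfig,
    codons: Optional[CodonString],
    registry: AlleleRegistry,
    mint: bool = True,
) -> str:
    """Return the registry name for a configuration, minting one if needed.

    Exact matches (same pQ configuration; same codons when codons are known on
    both sides) return the existing name.  A new length gets the bare
    ``opa{total}``; a taken length with a different histidine position gets the
    next free letter; a matching pQ with a different codon string gets the next
    numeric suffix within its letter group.  Minted records are added to the
    registry.
    """
    same_pq = registry.by_config(config)
    if codons is not None:
        hit = registry.find_by_codons(codons)
        if hit is not None and hit.config == config:
            return hit.name
    if same_pq:
        known_codon_recs = [r for r in same_pq if r.codons is not None]
        if codons is None or not known_codon_recs:
            return same_pq[0].name
        # identical pQ, different codon history -> numeric suffix
        if not mint:
            return same_pq[0].name
        length, letter, number, _ = parse_allele_name(same_pq[0].name)
        letter = letter or "a"
        numbers = []
        for r in same_pq:
            _, _, n, _ = parse_allele_name(r.name)
            numbers.append(n if n is not None else 1)
        name = f"opa{config.total_residues}{letter}{max(numbers) + 1}"
        registry.add(AlleleRecord(name, config, codons))
        return name
    same_length = registry.by_length(config.total_residues)
    if not mint:
        raise KeyError(f"no registered allele for {config.pq_string}")
    if not same_length:
        name = f"opa{config.total_residues}"
    else:
        used = set()
        for r in same_length:
            _, letter, _, _ = parse_allele_name(r.name)
            used.add(letter or "a")
        for letter in "abcdefghijklmnopqrstuvwxyz":
            if letter not in used:
                break
        else:  # pragma: no cover - 26 same-length alleles
            raise RegistryIntegrityError("letter suffixes exhausted")
        name = f"opa{config.total_residues}{letter}"
    registry.add(AlleleRecord(name, config, codons))
    return name


# ---------------------------------------------------------------------------
# Slippage derivatives


def _gln_runs(codons: CodonString) -> list[tuple[int, int, str]]:
    """Maximal runs of >=2 identical glutamine codons as (start, end, codon)."""
    runs = []
    i = 0
    cs = codons.codons
    while i < len(cs):
        j = i
        while j < len(cs) and cs[j] == cs[i]:
            j += 1
        if cs[i] in GLN_CODONS and j - i >= 2:
            runs.append((i, j, cs[i]))
        i = j
    return runs


def _run_side(start: int, end: int, his_index: Optional[int], reference_left: int) -> str:
    """L/R label for a glutamine run relative to the histidine.

    Histidine-less alleles use the reference position the His occupies in the
    ancestral wild-type pattern; a run straddling that boundary takes the side
    holding the larger share of it (ties go left).
    """
    if his_index is not None:
        return "L" if start < his_index else "R"
    if end <= reference_left:
        return "L"
    if start >= reference_left:
        return "R"
    return "L" if (reference_left - start) >= (end - reference_left) else "R"


def slippage_neighbors(
    parent: AlleleRecord,
    max_del: int = 4,
    max_ins: int = 2,
    reference_left: int = REFERENCE_HIS_LEFT,
) -> set[AlleleRecord]:
    """All single-event slippage derivatives of ``parent``.

    Each derivative deletes (or inserts) 1..max codons within one run of >=2
    identical glutamine codons, on one side of the histidine; the derivative
    is named ``opa{newLength}{L|R}``.  Parents without an eligible run yield
    the empty set.
    """
    if parent.codons is None:
        raise ValueError("parent allele has no codon string")
    out: dict[tuple[str, tuple[str, ...]], AlleleRecord] = {}
    his = parent.codons.his_index
    for start, end, codon in _gln_runs(parent.codons):
        side = _run_side(start, end, his, reference_left)
        run_len = end - start
        for k in range(1, min(max_del, run_len - 1) + 1):
            new = parent.codons.codons[: end - k] + parent.codons.codons[end:]
            _register_neighbor(out, parent, new, side)
        for k in range(1, max_ins + 1):
            new = parent.codons.codons[:end] + (codon,) * k + parent.codons.codons[end:]
            _register_neighbor(out, parent, new, side)
    return set(out.values())


def _register_neighbor(out, parent, new_codons, side):
    cs = CodonString(new_codons)
    cfg = classify_codons(cs)
    name = f"opa{cfg.total_residues}{side}"
    out[(name, new_codons)] = AlleleRecord(
        name, cfg, cs, derived_from=(parent.name, side)
    )


def is_slippage_derivative(
    child: AlleleRecord | PqConfig,
    parent: AlleleRecord | PqConfig,
    max_del: int = 4,
    max_ins: int = 2,
) -> tuple[bool, Optional[str], Optional[int]]:
    """Is ``child`` reachable from ``parent`` by one single-side slippage event?

    Returns ``(flag, side, steps)``.  Slippage changes the length of one
    glutamine tract only; it never creates or removes the histidine, so a
    histidine mismatch is never a slippage relation.
    """
    c = child.config if isinstance(child, AlleleRecord) else child
    p = parent.config if isinstance(parent, AlleleRecord) else parent
    no = (False, None, None)
    if c.has_his != p.has_his:
        return no

    def within(delta: int) -> bool:
        return -max_del <= delta <= max_ins and delta != 0

    if c.has_his:
        if c.right_q == p.right_q and within(c.left_q - p.left_q):
            return True, "L", abs(c.left_q - p.left_q)
        if c.left_q == p.left_q and within(c.right_q - p.right_q):
            return True, "R", abs(c.right_q - p.right_q)
        return no
    # histidine-less: a single tract; side defaults to the reference-left run
    if within(c.left_q - p.left_q):
        return True, "L", abs(c.left_q - p.left_q)
    return no


def distinct_isoforms(alleles: Iterable[AlleleRecord]) -> set[str]:
    """Unique pQ isoforms (alleles differing only at the nucleotide level collapse)."""
    return {a.pq_string for a in alleles}


# ---------------------------------------------------------------------------
# Default registry

def default_codon_string(config: PqConfig, variant: int = 0,
                         reference_left: int = REFERENCE_HIS_LEFT) -> CodonString:
    """A deterministic placeholder codon pattern for a pQ configuration.

    The true nucleotide strings of the surveyed alleles are not bundled; this
    pattern reproduces their salient structure: a (CAG)7 run immediately left
    of the histidine (the locus of nearly all observed contractions, hence the
    predominance of "L" slippage variants) and shorter CAA-broken CAG runs to
    its right.  ``variant`` perturbs the right-side breaker period to model
    independently derived codon histories of the same isoform.
    """
    def left_part(n: int) -> list[str]:
        if n <= 7:
            return ["CAG"] * n
        prefix = ["CAA" if (n - 7 - 1 - i) % 2 == 0 else "CAG" for i in range(n - 7)]
        return prefix + ["CAG"] * 7

    def right_part(m: int, lead_break: bool) -> list[str]:
        period = max(2, 5 - variant)
        out: list[str] = []
        run = 0
        if lead_break and m > 0:
            out.append("CAA")
            m -= 1
        while len(out) < m + (1 if lead_break else 0):
            if run < period:
                out.append("CAG")
                run += 1
            else:
                out.append("CAA")
                run = 0
        return out

    if config.has_his:
        codons = left_part(config.left_q) + ["CAT"] + right_part(config.right_q, False)
    else:
        n_left = min(config.left_q, reference_left)
        codons = left_part(n_left) + right_part(config.left_q - n_left, True)
    return CodonString(tuple(codons))


#: The ten allele classes recovered from the 41-line DGRP survey.
DEFAULT_ALLELES: tuple[tuple[str, str, int], ...] = (
    ("opa23", "Q23", 0),
    ("opa31", "Q13HQ17", 0),
    ("opa32", "Q13HQ18", 0),
    ("opa33a", "Q14HQ18", 0),
    ("opa33b", "Q15HQ17", 0),
    ("opa34", "Q16HQ17", 0),
    ("opa35a1", "Q13HQ21", 0),
    ("opa35a2", "Q13HQ21", 1),
    ("opa36", "Q13HQ22", 0),
    ("opa37", "Q13HQ23", 0),
)


def default_registry() -> AlleleRegistry:
    """Registry of the surveyed DGRP alleles with placeholder codon patterns."""
    recs = []
    for name, pq, variant in DEFAULT_ALLELES:
        cfg = PqConfig.from_string(pq)
        recs.append(AlleleRecord(name, cfg, default_codon_string(cfg, variant),
                                 notes="placeholder codon pattern"))
    return AlleleRegistry(recs)


# ---------------------------------------------------------------------------
# Registry TSV round trip

def write_registry(registry: AlleleRegistry, path) -> None:
    import pandas as pd

    rows = []
    for r in registry:
        rows.append(
            {
                "name": r.name,
                "pq_string": r.pq_string,
                "third_position_string": r.codons.compact if r.codons else "",
                "his_index": "" if r.codons is None or r.codons.his_index is None
                             else r.codons.his_index + 1,  # 1-based within the run
                "notes": r.notes,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_registry(path) -> AlleleRegistry:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    recs = []
    for row in df.itertuples(index=False):
        cfg = PqConfig.from_string(row.pq_string)
        codons = CodonString.from_thirds(row.third_position_string) if row.third_position_string else None
        recs.append(AlleleRecord(row.name, cfg, codons, notes=row.notes))
    return AlleleRegistry(recs)
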