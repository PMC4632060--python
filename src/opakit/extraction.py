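"""Anchored extraction of the CAX repeat run from clone/assembly sequences.

Repeat alignments need non-repetitive flanking "anchor" sequence to start and
end in the right place, so a read (or clone insert) informs the repeat
genotype only if it spans anchor + repeats + anchor.  This module finds the
in-frame CAX codon run between configurable anchors on either strand, and
implements the minimum spanning-read-length criterion
(3 bp x n codons + anchor bp x 2 sides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import reverse_complement

from .alleles import CAX_CODONS, CodonString, classify_codons
from .errors import AmbiguousLocusError, MalformedRepeatError, NoLocusError


@dataclass(frozen=True)
class AnchorConfig:
    """Non-repetitive flanks bounding the repeat run.

    Matching allows up to ``max_mismatch`` substitutions per anchor and no
    indels (Sanger clone flanks are high quality).
    """

    left_anchor: str
    right_anchor: str
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.left_anchor or not self.right_anchor:
            raise ValueError("anchors must be non-empty")
        for anchor in (self.left_anchor, self.right_anchor):
            codons = [anchor[i : i + 3] for i in range(0, len(anchor) - 2, 3)]
            run = 0
            for c in codons:
                run = run + 1 if c.upper() in CAX_CODONS else 0
                if run >= 2:
                    raise ValueError(f"anchor {anchor!r} contains an in-frame CAX run")


@dataclass(frozen=True)
class RepeatLocus:
    """An extracted repeat run located on a source sequence.

    ``start``/``end`` are 0-based half-open coordinates on the forward strand
    of the input sequence; ``strand`` records which strand carried the
    anchored run.
    """

    sequence_id: str
    strand: str
    start: int
    end: int
    codons: CodonString

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def pq_string(self) -> str:
        return classify_codons(self.codons).pq_string


def _find_matches(seq: str, anchor: str, max_mismatch: int) -> list[int]:
    """Start positions where anchor matches with <= max_mismatch substitutions."""
    hits = []
    n, m = len(seq), len(anchor)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(seq[i : i + m], anchor):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def locate_and_extract(
    sequence: str,
    anchors: AnchorConfig,
    sequence_id: str = "",
) -> RepeatLocus:
    """Find the anchored in-frame CAX codon run, searching both strands.

    Raises :class:`NoLocusError` when no anchor pair brackets a run,
    :class:`MalformedRepeatError` when the bracketed region is out of frame or
    interrupted by non-CAX codons, and :class:`AmbiguousLocusError` when more
    than one candidate locus matches.
    """
    sequence = sequence.upper()
    if len(sequence) < len(anchors.left_anchor) + len(anchors.right_anchor) + 3:
        raise NoLocusError("sequence shorter than anchors plus one codon")
    candidates: list[RepeatLocus] = []
    malformed: list[str] = []
    anchored = False
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        lefts = _find_matches(seq, anchors.left_anchor.upper(), anchors.max_mismatch)
        rights = _find_matches(seq, anchors.right_anchor.upper(), anchors.max_mismatch)
        for li in lefts:
            run_start = li + len(anchors.left_anchor)
            for ri in rights:
                if ri <= run_start:
                    continue
                anchored = True
                gap = seq[run_start:ri]
                if len(gap) % 3 != 0:
                    malformed.append(f"{strand}:{run_start}-{ri} out of frame")
                    continue
                codons = [gap[i : i + 3] for i in range(0, len(gap), 3)]
                if not codons or any(c not in CAX_CODONS for c in codons):
                    malformed.append(f"{strand}:{run_start}-{ri} interrupted run")
                    continue
                if strand == "+":
                    start, end = run_start, ri
                else:
                    start, end = len(seq) - ri, len(seq) - run_start
                candidates.append(
                    RepeatLocus(sequence_id, strand, start, end, CodonString(tuple(codons)))
                )
    if len(candidates) > 1:
        raise AmbiguousLocusError(
            f"{len(candidates)} candidate repeat loci in {sequence_id!r}", candidates
        )
    if not candidates:
        if anchored and malformed:
            raise MalformedRepeatError(
                f"anchored region is not a clean CAX run in {sequence_id!r}: "
                + "; ".join(malformed)
            )
        raise NoLocusError(f"anchors not found in {sequence_id!r}")
    return candidates[0]


def min_spanning_read_length(n_codons: int, anchor_per_side: int) -> int:
    """Bases needed to span ``n_codons`` triplets plus an anchor on each side."""
    if n_codons < 0 or anchor_per_side < 0:
        raise ValueError("counts must be non-negative")
    return 3 * n_codons + 2 * anchor_per_side


def can_span(read_len: int, n_codons: int, anchor_per_side: int) -> bool:
    """True iff a read of ``read_len`` bases strictly exceeds the spanning minimum.

    Strict: a 75-nt read cannot span a locus needing exactly 75 bases.
    """
    return read_len > min_spanning_read_length(n_codons, anchor_per_side)


def extract_table(
    records: Iterable[tuple[str, str]],
    anchors: AnchorConfig,
):
    """Run :func:`locate_and_extract` over ``(id, sequence)`` pairs -> DataFrame.

    Sequences with no locus or a malformed run are reported with an ``error``
    column rather than aborting the batch.
    """
    import pandas as pd

    rows = []
    for seq_id, seq in records:
        try:
            locus = locate_and_extract(seq, anchors, sequence_id=seq_id)
        except (NoLocusError, MalformedRepeatError, AmbiguousLocusError) as exc:
            rows.append({"sequence_id": seq_id, "error": str(exc)})
            continue
        rows.append(
            {
                "sequence_id": seq_id,
                "strand": locus.strand,
                "start": locus.start,
                "end": locus.end,
                "n_codons": locus.n_codons,
                "pq_string": locus.pq_string,
                "third_position_string": locus.codons.compact,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
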