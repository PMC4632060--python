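"""File IO: FASTA, sample sheets, anchors, and tabular round trips."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extraction import AnchorConfig


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: clone_id, line_id, individual_id, sex."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"clone_id", "line_id", "individual_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_anchors(path) -> AnchorConfig:
    """Anchor config from a YAML key-value file."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return AnchorConfig(
        left_anchor=data["left_anchor"],
        right_anchor=data["right_anchor"],
        max_mismatch=int(data.get("max_mismatch", 1)),
    )


def read_foreign_alleles(path) -> dict[str, list[str]]:
    """Foreign-allele TSV (line_id, allele third-position string or pQ string)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.line_id, []).append(row.allele)
    return out
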