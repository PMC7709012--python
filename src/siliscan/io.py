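"""FASTA input/output and tab-separated screening reports.

Protein sequences are held as plain upper-case strings over the 20 canonical
amino acids plus ``X`` for masked/unknown residues (plant proteome releases
routinely contain them).  Trailing ``*`` stop symbols are stripped on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(CANONICAL + "X")

FASTA_WIDTH = 60


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: accession-like id, free-text description, residues."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, residue in enumerate(self.seq, start=1):
            if residue not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {residue!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().rstrip("*")
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Raises ValueError on an empty file, duplicate ids (the offending id is
    named) and residues outside the 20 canonical letters + X (1-based
    position reported).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        description = entry.description[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                id=entry.id,
                seq=_normalize(str(entry.seq), entry.id),
                description=description,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records wrapped at 60 columns."""
    entries = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WIDTH)
        writer.write_file(entries)


# --- tabular reports ------------------------------------------------------
#
# Screening-call dataclasses (siliscan.classify) expose ``as_row()`` plus a
# class-level ``REPORT_COLUMNS`` tuple; write_report just lays them out.
# All interval fields in rows are 1-based inclusive; absent values become
# empty cells, never dropped rows.


def calls_to_frame(calls: Sequence, columns: Sequence[str] | None = None) -> pd.DataFrame:
    if calls:
        columns = list(getattr(type(calls[0]), "REPORT_COLUMNS"))
        rows = [call.as_row() for call in calls]
        return pd.DataFrame(rows, columns=columns)
    if columns is None:
        raise ValueError("empty call list needs explicit columns for the header")
    return pd.DataFrame(columns=list(columns))


def write_report(
    calls: Sequence,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write one TSV row per call (header always present, '.' decimals)."""
    frame = calls_to_frame(calls, columns=columns)
    frame.to_csv(path, sep="\t", index=False, na_rep="")
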