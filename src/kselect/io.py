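"""FASTA input and TSV/BED output for selection results.

Coordinates in every output are 0-based half-open (BED convention).
"""

from __future__ import annotations

import os
from typing import Iterable, TextIO, Union

from Bio import SeqIO

from .selectors import SelectionResult

TSV_COLUMNS = ("seq_id", "start", "end", "kmer", "method")


def read_fasta(path: Union[str, os.PathLike]) -> list[tuple[str, str]]:
    """(id, uppercased sequence) per record; wrapped or unwrapped lines,
    case-insensitive.  Raises ValueError on an empty or non-FASTA file."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(os.fspath(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path!r}")
    for rid, seq in records:
        if not seq:
            raise ValueError(f"record {rid!r} in {path!r} has an empty sequence")
    return records


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO, width: int = 60):
    for rid, seq in records:
        handle.write(f">{rid}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_selection(result: SelectionResult, handle: TextIO,
                    format: str = "tsv") -> None:
    """Write a selection as TSV (seq_id, start, end, kmer, method) or
    BED3+1 (name = kmer); rows ordered by start position."""
    if format == "tsv":
        handle.write("\t".join(TSV_COLUMNS) + "\n")
        desc = result.method.describe()
        for p in result.positions:
            p = int(p)
            handle.write(f"{result.seq_id}\t{p}\t{p + result.k}\t"
                         f"{result.kmer_at(p)}\t{desc}\n")
    elif format == "bed":
        for p in result.positions:
            p = int(p)
            handle.write(f"{result.seq_id}\t{p}\t{p + result.k}\t{result.kmer_at(p)}\n")
    else:
        raise ValueError(f"unknown format {format!r} (tsv or bed)")


def read_selection_tsv(handle: TextIO) -> list[dict]:
    """Parse a TSV written by write_selection back into row dicts."""
    header = handle.readline().rstrip("\n").split("\t")
    if header != list(TSV_COLUMNS):
        raise ValueError(f"unexpected header {header}")
    rows = []
    for line in handle:
        if not line.strip():
            continue
        seq_id, start, end, kmer, method = line.rstrip("\n").split("\t")
        rows.append({"seq_id": seq_id, "start": int(start), "end": int(end),
                     "kmer": kmer, "method": method})
    return rows
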