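"""Shared readers and writers for the formats the pipeline consumes and emits.

FASTA and FASTQ go through Biopython's :mod:`Bio.SeqIO`; tabular data through
pandas. Sequence case is normalised to upper on read, and duplicate record ids
are an error (downstream stages key on ids).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import ReadSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "read_json",
    "write_json",
    "FastqFormatError",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ input (truncated record or length mismatch)."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(id, sequence), ...]``, upper-cased.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def read_fastq(path) -> ReadSet:
    """Read 4-line FASTQ (plain or .gz) into a :class:`ReadSet`.

    Raises :class:`FastqFormatError` with an approximate line number on a
    truncated record or a sequence/quality length mismatch.
    """
    triples: list[tuple[str, str, str]] = []
    n_done = 0
    try:
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                seq = str(rec.seq).upper()
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                triples.append((rec.id, seq, qual))
                n_done += 1
    except ValueError as exc:
        raise FastqFormatError(
            f"malformed FASTQ in {path} near line {4 * n_done + 1}: {exc}"
        ) from exc
    return ReadSet.from_triples(triples)


def write_fastq(reads, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_text(path, "wt") as handle:
        for rid, seq, qual in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_json(path):
    with open(path) as handle:
        return json.load(handle)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")
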