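"""Readers and writers: FASTA/FASTQ sequences, TSV count matrices,
reference sets. All writers emit UTF-8, tab-delimited text with a header."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .model import ESTRecord, ReferenceRecord, ReferenceSet, UniqueRead, canonical


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: str = "fasta") -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ, in file order.

    Sequences are validated against the {A,C,G,T,U,N} alphabet and stored in
    the canonical DNA form (U -> T). N is retained; downstream preprocessing
    decides its fate.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            try:
                seq = canonical(str(rec.seq))
            except ValueError as e:
                raise ValueError(f"record {rec.id!r}: {e}") from e
            out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with _open(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_ests(path, category: str) -> list[ESTRecord]:
    return [ESTRecord(rid, seq, category) for rid, seq in read_sequences(path)]


def read_reference_set(path, kind: str) -> ReferenceSet:
    """Load a reference FASTA. For structural RNAs and known miRNAs the
    family label is taken from the second whitespace token of the header if
    present (``>id family``), else from the id itself."""
    records = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            parts = rec.description.split()
            family = parts[1] if len(parts) > 1 else rec.id
            records.append(ReferenceRecord(rec.id, family, canonical(str(rec.seq))))
    return ReferenceSet(kind=kind, records=records)


def write_count_matrix(reads: Iterable[UniqueRead], path, libraries: list[str] | None = None) -> None:
    """One row per unique read: read_id, sequence, one column per library, total."""
    reads = list(reads)
    if libraries is None:
        libraries = sorted({lib for r in reads for lib in r.counts})
    if not libraries:
        raise ValueError("count matrix requires at least one library")
    rows = [
        {"read_id": r.id, "sequence": r.sequence,
         **{lib: r.counts.get(lib, 0) for lib in libraries},
         "total": r.total_count}
        for r in reads
    ]
    df = pd.DataFrame(rows, columns=["read_id", "sequence", *libraries, "total"])
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> list[UniqueRead]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sequence": str})
    if df["sequence"].duplicated().any():
        dup = df.loc[df["sequence"].duplicated(), "sequence"].iloc[0]
        raise ValueError(f"duplicate sequence row in count matrix: {dup!r}")
    libs = [c for c in df.columns if c not in ("read_id", "sequence", "total")]
    if not libs:
        raise ValueError("count matrix has no library columns")
    out = []
    for d in df.to_dict("records"):
        counts = {lib: int(d[lib]) for lib in libs if int(d[lib]) != 0}
        out.append(UniqueRead(id=str(d["read_id"]), sequence=str(d["sequence"]), counts=counts))
    return out
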