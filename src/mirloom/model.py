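"""Core domain types for reference-genome-free small RNA analysis.

The central container is :class:`UniqueRead`: a collapsed read sequence with
per-library occurrence counts. Reads are collapsed only when completely
identical in both length and sequence -- a single-nucleotide difference keeps
two reads distinct, so no sequence heterogeneity is lost in collapsing.

Sequences are stored in a canonical DNA alphabet (``T``, not ``U``); ``U`` is
accepted on input and re-emitted for RNA-facing reports. Coordinates are
0-based half-open internally and 1-based inclusive in human-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_BASES = frozenset("ACGTN")

_RNA2DNA = str.maketrans("Uu", "Tt")
_DNA2RNA = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def canonical(seq: str) -> str:
    """Uppercase DNA form of a sequence (U mapped to T)."""
    s = seq.translate(_RNA2DNA).upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in sequence {seq!r}")
    return s


def to_rna(seq: str) -> str:
    """RNA form (T mapped to U) for mature-miRNA-facing reports."""
    return seq.upper().translate(_DNA2RNA)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_RNA2DNA).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Library:
    """A sequencing library (one tissue); total_reads is the RPM denominator."""

    name: str
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")


@dataclass
class UniqueRead:
    """A collapsed read: one distinct sequence with per-library counts."""

    id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ESTRecord:
    """A transcript sequence used in lieu of a reference genome.

    The stored strand is the coding/plus strand; small-RNA sequencing here is
    strand-specific, so sense vs antisense placement is meaningful.
    """

    id: str
    sequence: str
    category: str  # "protein_coding" | "noncoding"

    def __post_init__(self) -> None:
        if self.category not in ("protein_coding", "noncoding"):
            raise ValueError(f"unknown EST category {self.category!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    family: str
    sequence: str


@dataclass
class ReferenceSet:
    """A labelled reference collection: contaminants, structural RNAs or
    known mature miRNAs. Family labels are required for the latter two."""

    kind: str  # "contaminant" | "structural_rna" | "known_mirna"
    records: list[ReferenceRecord] = field(default_factory=list)

    KINDS = ("contaminant", "structural_rna", "known_mirna")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.kind in ("structural_rna", "known_mirna"):
            for rec in self.records:
                if not rec.family:
                    raise ValueError(
                        f"record {rec.id!r}: family label required for {self.kind}"
                    )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AlignParams:
    """Alignment knobs for the annotation cascade.

    Score fields mirror the miRBase web-BLAST settings (+5/-4, word size 4);
    they only matter for the optional external tabular-alignment adapter --
    the internal search is exact/k-edit and score-free.
    """

    max_mismatches: int = 3
    max_edits: int = 3
    match_score: int = 5
    mismatch_score: int = 4
    word_size: int = 4

    def __post_init__(self) -> None:
        for f in ("max_mismatches", "max_edits", "match_score", "mismatch_score", "word_size"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def collapse_reads(reads_per_library: Mapping[str, Iterable[str]]) -> list[UniqueRead]:
    """Collapse identical reads into unique reads with per-library counts.

    Reads are merged only when completely identical in length and sequence.
    Ids are assigned deterministically from the sorted order of sequences so
    repeated runs produce identical output.
    """
    counts: dict[str, dict[str, int]] = {}
    for lib, reads in reads_per_library.items():
        for raw in reads:
            seq = canonical(raw)
            per_lib = counts.setdefault(seq, {})
            per_lib[lib] = per_lib.get(lib, 0) + 1
    out = []
    for i, seq in enumerate(sorted(counts), start=1):
        out.append(UniqueRead(id=f"UR{i:07d}", sequence=seq, counts=counts[seq]))
    return out


def expand_reads(reads: Iterable[UniqueRead]) -> dict[str, list[str]]:
    """Inverse of collapse: per-library lists with each sequence repeated
    count times (used by the idempotence property test)."""
    out: dict[str, list[str]] = {}
    for r in reads:
        for lib, n in r.counts.items():
            out.setdefault(lib, []).extend([r.sequence] * n)
    return out
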