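"""Read preprocessing ahead of annotation: 3' adapter trimming, poly-N and
homopolymer exclusion, length selection, low-count filtering and contaminant
removal.

The filters mirror a gel-selected (18-30 nt) strand-specific small RNA
protocol: reads seen fewer than four times across all libraries are treated
as likely sequencing artefacts, and reads matching contaminant genomes
(chloroplast, viral, bacterial) at 100% identity over their full length are
discarded regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import ReferenceSet, UniqueRead, canonical, revcomp


@dataclass
class PreprocessConfig:
    adapter_3prime: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 30
    min_total_count: int = 4
    min_adapter_overlap: int = 6
    # trailing single-base runs longer than this are trimmed; reads that are
    # entirely one base are dropped outright
    max_trailing_homopolymer: int = 8
    contaminant_refs: ReferenceSet | None = None

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_total_count < 1:
            raise ValueError("min_total_count must be >= 1")


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the longest read suffix that exactly matches a prefix of the
    3' adapter, requiring at least ``min_overlap`` matching bases. No match
    leaves the read unchanged."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = canonical(read)
    adapter = canonical(adapter)
    max_ov = min(len(read), len(adapter))
    for k in range(max_ov, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[:-k]
    return read


def drop_polyN_and_homopolymers(read: str, cfg: PreprocessConfig) -> tuple[str | None, str | None]:
    """Returns (kept sequence, None) or (None, drop reason).

    Reads containing N are excluded (masked low-quality segments); reads that
    are a single repeated base are dropped as homopolymer artefacts; trailing
    mono-nucleotide runs longer than the configured threshold are trimmed
    (poly-A tails and adapter-dimer remnants)."""
    seq = canonical(read)
    if not seq:
        return None, "empty"
    if "N" in seq:
        return None, "poly_N"
    if len(set(seq)) == 1:
        return None, "homopolymer"
    run_base = seq[-1]
    run = len(seq) - len(seq.rstrip(run_base))
    if run > cfg.max_trailing_homopolymer:
        seq = seq.rstrip(run_base)
    return seq, None


def length_filter(read: str, cfg: PreprocessConfig) -> bool:
    return cfg.min_len <= len(read) <= cfg.max_len


def low_count_filter(reads: Iterable[UniqueRead], min_total_count: int) -> list[UniqueRead]:
    """Retain exactly the unique reads observed >= min_total_count times in
    total across libraries. Counts are untouched."""
    if min_total_count < 1:
        raise ValueError("min_total_count must be >= 1")
    return [r for r in reads if r.total_count >= min_total_count]


def remove_contaminants(
    reads: Iterable[UniqueRead], refs: ReferenceSet
) -> tuple[list[UniqueRead], list[tuple[UniqueRead, str]]]:
    """Split reads into (kept, removed) by exact full-length substring match
    against either strand of any contaminant reference.

    This is the contract equivalent of parsing 100%-identity full-query-span
    hits out of a BLAST report. Contaminant removal is deliberately not
    strand-specific: chloroplast and viral reads can arise from either strand.
    """
    if refs is None or len(refs) == 0:
        raise ValueError("contaminant reference set is empty")
    strands = []
    for rec in refs:
        strands.append((rec.id, rec.sequence))
        strands.append((rec.id, revcomp(rec.sequence)))
    kept, removed = [], []
    for r in reads:
        hit = next((rid for rid, s in strands if r.sequence in s), None)
        if hit is None:
            kept.append(r)
        else:
            removed.append((r, hit))
    return kept, removed


def length_histogram(reads: Iterable[UniqueRead]) -> dict[int, tuple[int, int]]:
    """Length -> (unique_count, total_count). Unique tallies show sequence
    diversity per length class; totals show redundancy-weighted abundance."""
    out: dict[int, list[int]] = {}
    for r in reads:
        u, t = out.setdefault(len(r.sequence), [0, 0])
        out[len(r.sequence)] = [u + 1, t + r.total_count]
    return {k: (v[0], v[1]) for k, v in sorted(out.items())}


@dataclass
class PreprocessResult:
    reads: list[UniqueRead]
    library_totals: dict[str, int]
    audit: list[tuple[str, str, str]] = field(default_factory=list)  # (read/seq, reason, ref id)
    attrition: list[tuple[str, dict[str, int]]] = field(default_factory=list)


def preprocess_libraries(
    raw_reads_per_library: dict[str, Sequence[str]], cfg: PreprocessConfig
) -> PreprocessResult:
    """Full preprocessing pass: trim, drop poly-N/homopolymers, length-select,
    collapse, low-count filter, contaminant removal.

    ``library_totals`` are the post-filter per-library read totals used as
    RPM denominators downstream. ``attrition`` records per-stage totals.
    """
    from .model import collapse_reads

    audit: list[tuple[str, str, str]] = []
    cleaned: dict[str, list[str]] = {}
    for lib, reads in raw_reads_per_library.items():
        keep = []
        for raw in reads:
            seq = trim_adapter(raw, cfg.adapter_3prime, cfg.min_adapter_overlap)
            seq, reason = drop_polyN_and_homopolymers(seq, cfg)
            if seq is None:
                audit.append((raw, reason, ""))
                continue
            if not length_filter(seq, cfg):
                audit.append((raw, "length", ""))
                continue
            keep.append(seq)
        cleaned[lib] = keep

    attrition = [("input", {lib: len(v) for lib, v in raw_reads_per_library.items()}),
                 ("after_trim_and_quality", {lib: len(v) for lib, v in cleaned.items()})]

    unique = collapse_reads(cleaned)
    unique = low_count_filter(unique, cfg.min_total_count)
    attrition.append(("after_low_count_filter",
                      {lib: sum(r.counts.get(lib, 0) for r in unique) for lib in cleaned}))

    if cfg.contaminant_refs is not None and len(cfg.contaminant_refs) > 0:
        unique, removed = remove_contaminants(unique, cfg.contaminant_refs)
        audit.extend((r.id, "contaminant", rid) for r, rid in removed)
    attrition.append(("after_contaminant_removal",
                      {lib: sum(r.counts.get(lib, 0) for r in unique) for lib in cleaned}))

    totals = {lib: sum(r.counts.get(lib, 0) for r in unique) for lib in cleaned}
    return PreprocessResult(reads=unique, library_totals=totals, audit=audit, attrition=attrition)
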