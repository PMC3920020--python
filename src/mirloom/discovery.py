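"""Novel miRNA discovery.

Reads with no annotation beyond (possibly) a non-coding EST placement are
mapped perfectly onto non-coding ESTs, the host locus runs the full
precursor filter cascade, and -- decisively -- the opposite-arm miRNA*
sequence must itself be present in the sequenced libraries. Requiring the
star read implements the community (Meyers) annotation standard and is what
keeps the false-positive rate down: stem-loops are abundant, stem-loops with
a sequenced two-nucleotide-overhang partner strand are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import UniqueRead, to_rna
from .precursor import (FilterThresholds, MfeRegression, PrecursorCandidate,
                        evaluate_candidate, generate_candidates, keep_best_per_locus)
from .structure import star_sequence


@dataclass
class NovelMiRNA:
    mirna_id: str
    mature_read_id: str
    mature_sequence: str          # RNA alphabet
    arm: str                      # "5p" | "3p"
    precursor: PrecursorCandidate
    star_read_id: str
    star_sequence: str
    five_prime_base: str = ""

    def __post_init__(self) -> None:
        if not self.five_prime_base:
            self.five_prime_base = to_rna(self.mature_sequence[:1])


def find_novel_candidates(
    unmatched_reads: Iterable[UniqueRead],
    noncoding_ests,
    thresholds: FilterThresholds,
    reg: MfeRegression,
    min_len: int = 20,
    max_len: int = 24,
    temperature: float = 25.0,
) -> list[PrecursorCandidate]:
    """Perfect-placement candidates through the full cascade (mode=novel).

    Only reads within the mature-length window (default 20-24 nt) are
    considered; one candidate is kept per EST/strand locus (most abundant
    read wins).
    """
    reads = [r for r in unmatched_reads if min_len <= len(r.sequence) <= max_len]
    mature_set = [(r.id, r.sequence) for r in reads]
    counts = {r.id: r.total_count for r in reads}
    cands = generate_candidates(mature_set, noncoding_ests, mode="novel",
                                mature_counts=counts, temperature=temperature)
    cands = keep_best_per_locus(cands)
    for c in cands:
        evaluate_candidate(c, thresholds, reg)
    return cands


def star_evidence(candidate: PrecursorCandidate, reads: Iterable[UniqueRead],
                  max_star_shift: int = 0) -> UniqueRead | None:
    """Search the libraries for the miRNA* counterpart of a passed candidate.

    The star span comes from the duplex on the trimmed structure; a read
    matches when equal to the star sequence, or (max_star_shift > 0) to the
    star with its ends shifted by up to that many nt. The highest-count
    match wins; default is exact.
    """
    if not candidate.passed or candidate.trimmed is None or candidate.duplex is None:
        return None
    pt = candidate.trimmed.pair_table
    # recompute the duplex on the trimmed structure for exact star coordinates
    from .structure import NoDuplexError, derive_star

    try:
        duplex = derive_star(pt, candidate.mature_span)
    except NoDuplexError:
        return None
    star_rna = star_sequence(pt, duplex)
    star_dna = star_rna.replace("U", "T")
    accepted = set()
    n = len(star_dna)
    for d5 in range(-max_star_shift, max_star_shift + 1):
        for d3 in range(-max_star_shift, max_star_shift + 1):
            lo, hi = duplex.star[0] + d5, duplex.star[1] + d3
            if 0 <= lo < hi <= len(pt):
                accepted.add(pt.sequence[lo:hi].replace("U", "T"))
    best = None
    for r in reads:
        if r.sequence in accepted:
            if best is None or r.total_count > best.total_count:
                best = r
    return best


def call_novel_mirnas(
    unmatched_reads: Iterable[UniqueRead],
    noncoding_ests,
    thresholds: FilterThresholds,
    reg: MfeRegression,
    all_reads: Iterable[UniqueRead] | None = None,
    max_star_shift: int = 0,
    min_len: int = 20,
    max_len: int = 24,
    temperature: float = 25.0,
) -> list[NovelMiRNA]:
    """Full novel-miRNA calling: candidates + mandatory star evidence.

    ``all_reads`` is the post-filter read set searched for stars (defaults
    to the unmatched set). Ids follow the PA-miR<n>-5p/3p style: sequential
    per precursor, arm from the mature's position relative to the loop.
    """
    unmatched_reads = list(unmatched_reads)
    star_pool = list(all_reads) if all_reads is not None else unmatched_reads
    cands = find_novel_candidates(unmatched_reads, noncoding_ests, thresholds, reg,
                                  min_len=min_len, max_len=max_len, temperature=temperature)
    out = []
    serial = 0
    for cand in sorted((c for c in cands if c.passed),
                       key=lambda c: (-c.mature_count, c.est_id, c.mature_span)):
        star = star_evidence(cand, star_pool, max_star_shift=max_star_shift)
        if star is None:
            continue
        serial += 1
        pt = cand.trimmed.pair_table
        s, e = cand.mature_span
        # arm: mature before the terminal loop midpoint -> 5p
        from .structure import hairpin_metrics

        hm = hairpin_metrics(pt)
        mid = len(pt) / 2
        if hm.stems:
            s5, e5, s3, e3 = hm.stems[0]
            mid = (e5 + s3) / 2
        arm = "5p" if (s + e) / 2 < mid else "3p"
        out.append(NovelMiRNA(
            mirna_id=f"nov-miR{serial}-{arm}",
            mature_read_id=cand.mature_read_id,
            mature_sequence=to_rna(cand.mature_sequence),
            arm=arm,
            precursor=cand,
            star_read_id=star.id,
            star_sequence=to_rna(star.sequence),
        ))
    return out


def five_prime_U_fraction(matures: Iterable) -> tuple[int, int]:
    """(# starting with U, total) over distinct mature reads.

    Accepts NovelMiRNA objects, (read_id, sequence) pairs, or bare
    sequences; duplicates (same read id) are counted once.
    """
    seen: dict[str, str] = {}
    for i, m in enumerate(matures):
        if isinstance(m, NovelMiRNA):
            key, seq = m.mature_read_id, m.mature_sequence
        elif isinstance(m, tuple):
            key, seq = m
        else:
            key, seq = f"_{i}_{m}", m
        seen.setdefault(key, seq)
    total = len(seen)
    count_u = sum(1 for s in seen.values() if s[:1].upper() in ("U", "T"))
    return count_u, total
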