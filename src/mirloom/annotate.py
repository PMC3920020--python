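"""The annotation cascade: every post-filter unique read is assigned exactly
one category, in a fixed order of precedence:

1. perfect, full-length, *sense-strand* hit to a protein-coding EST ->
   ``protein_coding`` (degraded mRNA; sequencing is strand-specific, so an
   antisense-only hit does not count);
2. perfect hit to a non-coding EST (either strand) is recorded but the read
   continues through the cascade;
3. structural-RNA hit within ``max_edits`` discrepancies (gaps plus
   mismatches) -> the reference family's class (rRNA/tRNA/snRNA/snoRNA/
   other_sRNA);
4. known-miRNA hit within ``max_mismatches`` substitutions (ungapped) ->
   ``miRNA`` with its family;
5. reads holding only a non-coding-EST record -> ``noncoding_est``;
6. otherwise ``unmatched``.

Conserved-miRNA family labels are derived from reference names by stripping
the species prefix and letter/arm suffixes (ath-miR156a-5p -> miR156).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import edlib

from .model import AlignParams, ESTRecord, ReferenceSet, UniqueRead, revcomp

STRUCTURAL_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "other_sRNA")
CATEGORIES = ("protein_coding", "noncoding_est", *STRUCTURAL_CLASSES, "miRNA", "unmatched")


@dataclass
class Hit:
    ref_id: str
    strand: str          # "+" | "-"
    position: int        # 0-based start on the reference plus strand
    mismatches: int
    gaps: int


@dataclass
class AnnotationRecord:
    read_id: str
    category: str
    evidence: Hit | None = None
    family: str | None = None
    noncoding_hits: list = field(default_factory=list)


@dataclass
class FamilyCount:
    family: str
    reads: dict[str, int] = field(default_factory=dict)         # per-library totals
    unique_reads: dict[str, int] = field(default_factory=dict)  # per-library distinct reads


def mirna_family(ref_name: str) -> str:
    """Family label from a mature-miRNA reference name.

    ath-miR156a-5p -> miR156; osa-miR156b -> miR156; miR-466 -> miR-466.
    Unparsable names fall back to the raw name.
    """
    m = re.search(r"(miR)-?(\d+)", ref_name, flags=re.IGNORECASE)
    if m is None:
        return ref_name
    keep_dash = "-" in m.group(0)
    return f"miR{'-' if keep_dash else ''}{m.group(2)}"


def match_sense_perfect(read: UniqueRead, ests: Iterable[ESTRecord]) -> Hit | None:
    """Perfect full-length hit on the stored (coding) strand only."""
    for est in ests:
        pos = est.sequence.find(read.sequence)
        if pos >= 0:
            return Hit(ref_id=est.id, strand="+", position=pos, mismatches=0, gaps=0)
    return None


def match_perfect_both_strands(seq: str, ests: Iterable[ESTRecord]) -> list[Hit]:
    hits = []
    for est in ests:
        pos = est.sequence.find(seq)
        if pos >= 0:
            hits.append(Hit(est.id, "+", pos, 0, 0))
            continue
        pos = est.sequence.find(revcomp(seq))
        if pos >= 0:
            hits.append(Hit(est.id, "-", pos, 0, 0))
    return hits


def _hamming_best(read: str, ref: str, max_mm: int) -> tuple[int, int] | None:
    """Best (mismatches, position) of an ungapped full-read placement."""
    n, m = len(read), len(ref)
    if n > m:
        return None
    best = None
    for off in range(m - n + 1):
        mm = sum(1 for a, b in zip(read, ref[off:off + n]) if a != b)
        if best is None or mm < best[0]:
            best = (mm, off)
            if mm == 0:
                break
    if best is not None and best[0] <= max_mm:
        return best
    return None


def match_with_edits(read: str, ref: str, max_edits: int, gapped: bool = True) -> Hit | None:
    """Best semi-global placement of the full read within ref (both strands).

    gapped=True minimises edits (gaps plus mismatches, via edlib infix
    alignment); gapped=False allows substitutions only. Returns the hit only
    when the edit count is within ``max_edits``; ties favour the plus strand.
    """
    best: Hit | None = None
    for strand, target in (("+", ref), ("-", revcomp(ref))):
        if gapped:
            res = edlib.align(read, target, mode="HW", task="path", k=max_edits)
            if res["editDistance"] < 0:
                continue
            cigar = res["cigar"] or ""
            mism = sum(int(n) for n, op in re.findall(r"(\d+)([=XIDM])", cigar) if op == "X")
            gaps = sum(int(n) for n, op in re.findall(r"(\d+)([=XIDM])", cigar) if op in "ID")
            start, end = res["locations"][0]
            pos = start if strand == "+" else len(ref) - (end + 1)
            cand = Hit(ref_id="", strand=strand, position=pos, mismatches=mism, gaps=gaps)
        else:
            r = _hamming_best(read, target, max_edits)
            if r is None:
                continue
            mism, off = r
            pos = off if strand == "+" else len(ref) - (off + len(read))
            cand = Hit(ref_id="", strand=strand, position=pos, mismatches=mism, gaps=0)
        if best is None or (cand.mismatches + cand.gaps) < (best.mismatches + best.gaps):
            best = cand
    return best


def _best_ref_hit(seq: str, records, max_edits: int, gapped: bool) -> tuple[Hit, object] | None:
    """Best hit across a reference set; ties broken by fewest mismatches then
    reference order (affects evidence only, never the category)."""
    best = None
    for rec in records:
        h = match_with_edits(seq, rec.sequence, max_edits, gapped=gapped)
        if h is None:
            continue
        h.ref_id = rec.id
        key = (h.mismatches + h.gaps, h.mismatches)
        if best is None or key < best[0]:
            best = (key, h, rec)
            if key == (0, 0):
                break
    if best is None:
        return None
    return best[1], best[2]


def classify_reads(
    reads: Iterable[UniqueRead],
    coding_ests: list[ESTRecord],
    noncoding_ests: list[ESTRecord],
    structural_refs: ReferenceSet,
    mirna_refs: ReferenceSet,
    params: AlignParams | None = None,
) -> list[AnnotationRecord]:
    """Run the full cascade; every read gets exactly one category."""
    if params is None:
        params = AlignParams()
    for name, refset in (("structural_refs", structural_refs), ("mirna_refs", mirna_refs)):
        if refset is None:
            raise ValueError(f"missing reference set: {name}")
    if coding_ests is None or noncoding_ests is None:
        raise ValueError("missing reference set: ESTs")

    out = []
    for read in reads:
        # step 1: degraded mRNA (sense-strand perfect hit on coding EST)
        hit = match_sense_perfect(read, coding_ests)
        if hit is not None:
            out.append(AnnotationRecord(read.id, "protein_coding", evidence=hit))
            continue
        # step 2: record non-coding EST placements (either strand), continue
        nc_hits = match_perfect_both_strands(read.sequence, noncoding_ests)
        # step 3: structural RNA (gapped, <= max_edits discrepancies)
        res = _best_ref_hit(read.sequence, structural_refs, params.max_edits, gapped=True)
        if res is not None:
            hit, rec = res
            cls = rec.family if rec.family in STRUCTURAL_CLASSES else "other_sRNA"
            out.append(AnnotationRecord(read.id, cls, evidence=hit, family=rec.family,
                                        noncoding_hits=nc_hits))
            continue
        # step 4: known miRNA (ungapped, <= max_mismatches substitutions)
        res = _best_ref_hit(read.sequence, mirna_refs, params.max_mismatches, gapped=False)
        if res is not None:
            hit, rec = res
            fam = mirna_family(rec.family or rec.id)
            out.append(AnnotationRecord(read.id, "miRNA", evidence=hit, family=fam,
                                        noncoding_hits=nc_hits))
            continue
        # steps 5/6
        if nc_hits:
            out.append(AnnotationRecord(read.id, "noncoding_est", evidence=nc_hits[0],
                                        noncoding_hits=nc_hits))
        else:
            out.append(AnnotationRecord(read.id, "unmatched"))
    return out


def aggregate_families(
    records: Iterable[AnnotationRecord], reads: Iterable[UniqueRead],
    merge_map: dict[str, str] | None = None,
) -> list[FamilyCount]:
    """Per-family totals: read counts and unique-read counts per library.

    ``merge_map`` optionally pools families (e.g. {"miR157": "miR156"}) for
    users who treat near-identical families as one.
    """
    by_id = {r.id: r for r in reads}
    fams: dict[str, FamilyCount] = {}
    for rec in records:
        if rec.category != "miRNA" or rec.family is None:
            continue
        fam = (merge_map or {}).get(rec.family, rec.family)
        fc = fams.setdefault(fam, FamilyCount(family=fam))
        read = by_id.get(rec.read_id)
        if read is None:
            continue
        for lib, n in read.counts.items():
            fc.reads[lib] = fc.reads.get(lib, 0) + n
            fc.unique_reads[lib] = fc.unique_reads.get(lib, 0) + 1
    return sorted(fams.values(), key=lambda f: f.family)


def category_table(records: Iterable[AnnotationRecord], reads: Iterable[UniqueRead]):
    """Category x library matrix of total and unique read counts."""
    import pandas as pd

    by_id = {r.id: r for r in reads}
    rows = []
    for rec in records:
        read = by_id[rec.read_id]
        for lib, n in read.counts.items():
            rows.append({"category": rec.category, "library": lib, "total": n, "unique": 1})
    if not rows:
        return pd.DataFrame(columns=["category", "library", "total", "unique"])
    df = pd.DataFrame(rows)
    return df.groupby(["category", "library"], as_index=False).sum()
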