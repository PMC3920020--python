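"""miRNA target prediction.

Method 1 (complementarity): plant miRNAs pair near-perfectly with their
targets, so an ungapped antisense scan of each transcript suffices. Only
Watson-Crick pairs count -- a G:U wobble is a mismatch here, unlike in
structure folding. A site qualifies when the aligned window covers miRNA
positions 2-12 (1-based from the miRNA 5' end), spans more than 16 nt
(>= 17 contiguous aligned positions) and holds at most 3 mismatches.

Method 2 (homology transfer): transcripts whose best protein-level hit in a
model-organism database is a known miRNA target inherit that target call,
restricted to miRNA families actually observed in the libraries.

A transcript carrying two or more non-overlapping sites for one miRNA is
flagged as a candidate trans-acting siRNA (TAS-like) locus -- the canonical
example being the two miR390 sites flanking the tasiR-ARF region of TAS3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import ESTRecord, canonical

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int                # 0-based on the transcript sense strand
    end: int                  # half-open
    alignment_length: int
    mismatches: int
    covers_2_12: bool
    mirna_window: tuple[int, int]   # aligned miRNA positions, 1-based closed

    @property
    def span_1based(self) -> tuple[int, int]:
        return (self.start + 1, self.end)


def _window_mismatches(mirna: str, transcript: str, offset: int, a: int, b: int) -> int:
    """Mismatches when miRNA positions [a, b] (1-based) pair antisense with
    the transcript window ending at offset + len(mirna) - a ... transcript
    runs 5'->3', the miRNA binds it 3'->5', so miRNA position p (1-based from
    the miRNA 5' end) faces transcript position offset + (len(mirna) - p)."""
    n = len(mirna)
    mm = 0
    for p in range(a, b + 1):
        t = transcript[offset + (n - p)]
        q = mirna[p - 1]
        if (q, t) not in _WC:
            mm += 1
    return mm


def complementarity_scan(
    mirna_id: str,
    mirna: str,
    transcripts: Iterable[ESTRecord],
    max_mismatches: int = 3,
    min_alignment_length: int = 17,
    seed_start: int = 2,
    seed_end: int = 12,
    max_mismatches_seed: int | None = None,
) -> list[TargetSite]:
    """Ungapped antisense scan of every offset on each transcript's sense
    strand; overlapping qualifying windows are merged to the best (fewest
    mismatches, then longest, then leftmost).

    Windows must begin and end on a Watson-Crick match (an ungapped local
    alignment never extends past a terminal mismatch), so a stretch of
    complementarity shorter than the length floor cannot be padded into a
    qualifying site by appending mismatched positions."""
    mirna = canonical(mirna)
    n = len(mirna)
    if n < 13:
        raise ValueError("miRNA must be at least 13 nt")
    out = []
    for tr in transcripts:
        seq = tr.sequence
        sites = []
        for offset in range(0, len(seq) - n + 1):
            best = None
            # enumerate aligned miRNA sub-windows [a, b] covering the seed
            for a in range(1, seed_start + 1):
                if (mirna[a - 1], seq[offset + (n - a)]) not in _WC:
                    continue
                for b in range(max(seed_end, a + min_alignment_length - 1), n + 1):
                    if b - a + 1 < min_alignment_length:
                        continue
                    if (mirna[b - 1], seq[offset + (n - b)]) not in _WC:
                        continue
                    mm = _window_mismatches(mirna, seq, offset, a, b)
                    if mm > max_mismatches:
                        continue
                    if max_mismatches_seed is not None:
                        seed_mm = _window_mismatches(mirna, seq, offset, seed_start, seed_end)
                        if seed_mm > max_mismatches_seed:
                            continue
                    key = (mm, -(b - a + 1), a)
                    if best is None or key < best[0]:
                        best = (key, a, b, mm)
            if best is None:
                continue
            _, a, b, mm = best
            start = offset + (n - b)
            end = offset + (n - a) + 1
            sites.append(TargetSite(mirna_id=mirna_id, transcript_id=tr.id,
                                    start=start, end=end, alignment_length=b - a + 1,
                                    mismatches=mm, covers_2_12=True,
                                    mirna_window=(a, b)))
        out.extend(_merge_overlapping(sites))
    return out


def _merge_overlapping(sites: list[TargetSite]) -> list[TargetSite]:
    """One site per physical locus: overlapping windows collapse to the best
    (fewest mismatches, then longest, then leftmost)."""
    sites = sorted(sites, key=lambda s: s.start)
    clusters: list[list[TargetSite]] = []
    for s in sites:
        if clusters and s.start < clusters[-1][-1].end and s.end > clusters[-1][0].start:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return [min(cl, key=lambda s: (s.mismatches, -s.alignment_length, s.start))
            for cl in clusters]


def alignment_strings(mirna: str, transcript: str, site: TargetSite) -> tuple[str, str, str]:
    """miRNA 5'->3' over site 3'->5' with pairing marks (| = Watson-Crick)."""
    a, b = site.mirna_window
    mir = canonical(mirna)[a - 1:b]
    tgt = canonical(transcript)[site.start:site.end][::-1]  # 3'->5'
    marks = "".join("|" if (m, t) in _WC else " " for m, t in zip(mir, tgt))
    return mir, marks, tgt


@dataclass
class HomologyTransferInput:
    est_besthit: pd.DataFrame    # est_id, model_gene_id, evalue
    known_targets: pd.DataFrame  # family, model_gene_id
    evalue_cutoff: float = 1e-30


def homology_transfer(inp: HomologyTransferInput,
                      mirnas_present: set[str]) -> list[tuple[str, str]]:
    """(est_id, family) pairs: best model-organism hits below the e-value
    cutoff joined with the known-target table, restricted to families
    observed in the libraries."""
    for col in ("est_id", "model_gene_id", "evalue"):
        if col not in inp.est_besthit.columns:
            raise ValueError(f"est_besthit missing column {col!r}")
    for col in ("family", "model_gene_id"):
        if col not in inp.known_targets.columns:
            raise ValueError(f"known_targets missing column {col!r}")
    hits = inp.est_besthit[inp.est_besthit["evalue"] <= inp.evalue_cutoff]
    joined = hits.merge(inp.known_targets, on="model_gene_id")
    joined = joined[joined["family"].isin(mirnas_present)]
    return sorted(set(zip(joined["est_id"], joined["family"])))


def merge_methods(sites: Sequence[TargetSite], transfers: Sequence[tuple[str, str]],
                  site_families: dict[str, str] | None = None) -> pd.DataFrame:
    """Unified target table keyed by (family, transcript) with method flags.

    ``site_families`` maps mirna_id -> family for the complementarity sites
    (identity when the scan already ran per family)."""
    fam = site_families or {}
    m1 = {(fam.get(s.mirna_id, s.mirna_id), s.transcript_id) for s in sites}
    # transfer rows are (est, family); normalise to (family, est)
    m2 = {(family, est) for est, family in transfers}
    rows = []
    for family, est in sorted(m1 | m2):
        in1, in2 = (family, est) in m1, (family, est) in m2
        rows.append({"family": family, "transcript_id": est,
                     "method1": in1, "method2": in2,
                     "method": "both" if in1 and in2 else ("method1" if in1 else "method2")})
    return pd.DataFrame(rows, columns=["family", "transcript_id", "method1", "method2", "method"])


def detect_dual_site_transcripts(
    mirna_id: str, mirna: str, transcripts: Iterable[ESTRecord], min_sites: int = 2,
    **scan_kwargs,
) -> list[tuple[str, list[TargetSite]]]:
    """Transcripts with >= min_sites non-overlapping qualifying sites for the
    same miRNA (TAS-like loci), sites in coordinate order."""
    sites = complementarity_scan(mirna_id, mirna, transcripts, **scan_kwargs)
    by_tr: dict[str, list[TargetSite]] = {}
    for s in sites:
        by_tr.setdefault(s.transcript_id, []).append(s)
    out = []
    for tid, ss in sorted(by_tr.items()):
        ss.sort(key=lambda s: s.start)
        if len(ss) >= min_sites:
            out.append((tid, ss))
    return out
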