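"""Stem-loop miRNA precursor prediction from non-coding transcripts.

A candidate is an EST locus carrying a mature small-RNA placement. Both the
forward and reverse-complement strands are folded; the mature footprint must
sit in the stem (not the loop), a miRNA* duplex is derived, the sequence is
trimmed to the duplex plus 10 nt beyond the terminal mature/miRNA* base pair
and refolded, and the trimmed hairpin runs an ordered filter cascade:

1. mature in the stem, not the loop;
2. MFE inside a length-conditional prediction interval (MFE regressed on
   length over a training set of accepted hairpins -- absolute MFE cutoffs
   are meaningless across lengths);
3. terminal loop <= 15 nt;
4. branches <= 6;
5. core-region bulges: at most 1, size at most 2;
6. longest run of continuous unpaired core residues <= 4;
7. no loop/branch inside the core region;
8. total unpaired core residues within a length-graded allowance
   (<=17 bp core: 1; 18: 2; 19: 3; 20: 4; >20: 5).

The verdict records the first failing rule. A shuffle benchmark (permuting
each positive while preserving nucleotide composition) estimates sensitivity
and specificity of the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ESTRecord, UniqueRead, revcomp
from .structure import (CoreRegion, CoreRejection, Duplex, NoDuplexError, PairTable,
                        TrimResult, derive_star, fold, hairpin_metrics, locate_core,
                        star_sequence, trim_precursor)


@dataclass
class MfeRegression:
    """OLS regression of MFE on sequence length with everything needed for a
    two-sided prediction interval at a new length."""

    slope: float
    intercept: float
    n: int
    residual_sd: float
    mean_length: float
    sxx: float
    confidence: float = 0.95
    backend: str = "builtin"
    # degenerate perfectly-linear training widens the band by this epsilon
    epsilon: float = 1e-6

    @property
    def t_quantile(self) -> float:
        return float(stats.t.ppf(1 - (1 - self.confidence) / 2, self.n - 2))

    def predict(self, length: float) -> float:
        return self.intercept + self.slope * length

    def interval(self, length: float) -> tuple[float, float]:
        sd = max(self.residual_sd, self.epsilon)
        half = self.t_quantile * sd * np.sqrt(
            1 + 1 / self.n + (length - self.mean_length) ** 2 / self.sxx
        )
        mid = self.predict(length)
        return (mid - half, mid + half)


class InsufficientTraining(ValueError):
    pass


def fit_mfe_regression(training: Sequence[tuple[float, float]],
                       confidence: float = 0.95, backend: str = "builtin") -> MfeRegression:
    """Fit MFE ~ length by ordinary least squares.

    ``training`` holds (length, mfe) pairs from accepted hairpins folded with
    the *same backend* later used for scoring; energies from different
    engines are not interchangeable.
    """
    if len(training) < 3:
        raise InsufficientTraining("need at least 3 training points")
    L = np.array([t[0] for t in training], dtype=float)
    y = np.array([t[1] for t in training], dtype=float)
    sxx = float(np.sum((L - L.mean()) ** 2))
    if sxx == 0:
        raise InsufficientTraining("lengths have zero variance")
    slope = float(np.sum((L - L.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * L.mean())
    resid = y - (intercept + slope * L)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / (len(L) - 2)))
    return MfeRegression(slope=slope, intercept=intercept, n=len(L),
                         residual_sd=residual_sd, mean_length=float(L.mean()),
                         sxx=sxx, confidence=confidence, backend=backend)


def mfe_within_pi(reg: MfeRegression, length: float, mfe: float,
                  one_sided: bool = False) -> bool:
    """Two-sided prediction-interval membership (a one-sided lower bound --
    reject only insufficiently stable structures -- is available but off by
    default)."""
    lo, hi = reg.interval(length)
    if one_sided:
        return mfe <= hi
    return lo <= mfe <= hi


@dataclass
class FilterThresholds:
    max_loop: int = 15
    max_branches: int = 6
    max_core_bulges: int = 1
    max_core_bulge_size: int = 2
    max_continuous_unpaired: int = 4
    # core length (bp) -> maximum unpaired residues
    mismatch_allowance: dict = field(default_factory=lambda: {17: 1, 18: 2, 19: 3, 20: 4, 21: 5})

    def allowance(self, core_length_bp: int) -> int:
        if core_length_bp <= 17:
            return self.mismatch_allowance[17]
        return self.mismatch_allowance[min(core_length_bp, 21)]


@dataclass
class PrecursorCandidate:
    est_id: str
    strand: str                      # "+" | "-"
    mature_read_id: str
    mature_sequence: str
    mature_span: tuple[int, int]     # on the folded strand, 0-based half-open
    strand_sequence: str             # the folded EST strand
    provenance: str                  # conserved_match | est_vs_mirbase | novel
    mature_count: int = 0
    pair_table: PairTable | None = None
    duplex: Duplex | None = None
    trimmed: TrimResult | None = None
    core: CoreRegion | None = None
    mfe: float | None = None
    verdict: str | None = None       # "pass" | "fail:<rule>"
    family: str | None = None

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"

    @property
    def trimmed_length(self) -> int:
        return len(self.trimmed.sequence) if self.trimmed else 0


PROVENANCES = ("conserved_match", "est_vs_mirbase", "novel")


def _placements(mature: str, est: ESTRecord, max_edits: int) -> list[tuple[str, str, int]]:
    """(strand, strand_sequence, start) placements of the mature on either
    strand of the EST. max_edits=0 means perfect substring matches."""
    out = []
    for strand, seq in (("+", est.sequence), ("-", revcomp(est.sequence))):
        if max_edits == 0:
            start = 0
            while True:
                pos = seq.find(mature, start)
                if pos < 0:
                    break
                out.append((strand, seq, pos))
                start = pos + 1
        else:
            import edlib

            res = edlib.align(mature, seq, mode="HW", task="locations", k=max_edits)
            if res["editDistance"] >= 0:
                seen = set()
                for (s_, e_) in res["locations"]:
                    if s_ in seen:
                        continue
                    seen.add(s_)
                    out.append((strand, seq, s_))
    return out


def build_candidate(est_id: str, strand: str, strand_seq: str, mature_span: tuple[int, int],
                    read_id: str, provenance: str, mature_count: int = 0,
                    family: str | None = None, temperature: float = 25.0,
                    flank: int = 10) -> PrecursorCandidate:
    """Fold, locate the core, derive the star, trim and refold one placement.

    Structural failures (mature in loop, no duplex) are recorded in the
    verdict rather than raised, so the audit keeps every placement.
    """
    s, e = mature_span
    cand = PrecursorCandidate(est_id=est_id, strand=strand, mature_read_id=read_id,
                              mature_sequence=strand_seq[s:e], mature_span=mature_span,
                              strand_sequence=strand_seq, provenance=provenance,
                              mature_count=mature_count, family=family)
    pt = fold(strand_seq, temperature=temperature)
    cand.pair_table = pt
    try:
        locate_core(pt, mature_span)
        duplex = derive_star(pt, mature_span)
    except CoreRejection as e_:
        cand.verdict = f"fail:{e_.reason}"
        return cand
    except NoDuplexError:
        cand.verdict = "fail:no_duplex"
        return cand
    cand.duplex = duplex
    tr = trim_precursor(pt, duplex, flank=flank)
    cand.trimmed = tr
    cand.mfe = tr.pair_table.mfe
    new_span = (mature_span[0] - tr.offset, mature_span[1] - tr.offset)
    cand.mature_span = new_span
    try:
        cand.core = locate_core(tr.pair_table, new_span)
    except CoreRejection as e_:
        cand.verdict = f"fail:{e_.reason}"
    return cand


def generate_candidates(
    mature_set: Iterable[tuple[str, str]],
    noncoding_ests: Iterable[ESTRecord],
    mode: str,
    mature_counts: dict[str, int] | None = None,
    families: dict[str, str] | None = None,
    temperature: float = 25.0,
    max_edits_mirbase: int = 3,
) -> list[PrecursorCandidate]:
    """Pre-filter candidates for every qualifying (mature, EST, strand)
    placement: perfect matches for conserved_match/novel modes, up to
    ``max_edits_mirbase`` discrepancies for est_vs_mirbase mode.

    Overlapping placements of several reads on one EST are deduplicated
    later (keep_best_per_locus): the most abundant read is taken as the
    mature form.
    """
    if mode not in PROVENANCES:
        raise ValueError(f"unknown mode {mode!r}")
    max_edits = 0 if mode in ("conserved_match", "novel") else max_edits_mirbase
    out = []
    for read_id, mature in mature_set:
        for est in noncoding_ests:
            if est.category != "noncoding":
                continue
            for strand, seq, pos in _placements(mature, est, max_edits):
                cand = build_candidate(
                    est.id, strand, seq, (pos, pos + len(mature)), read_id, mode,
                    mature_count=(mature_counts or {}).get(read_id, 0),
                    family=(families or {}).get(read_id), temperature=temperature,
                )
                out.append(cand)
    return out


def evaluate_candidate(cand: PrecursorCandidate, thresholds: FilterThresholds,
                       reg: MfeRegression) -> str:
    """Ordered filter cascade; the verdict is 'pass' or 'fail:<first rule>'."""
    if cand.verdict is not None and cand.verdict.startswith("fail"):
        return cand.verdict
    if cand.core is None or cand.trimmed is None:
        cand.verdict = "fail:in_loop"
        return cand.verdict
    if reg.backend != cand.trimmed.pair_table.backend:
        raise ValueError(
            f"MFE regression trained with backend {reg.backend!r} cannot score "
            f"structures folded with {cand.trimmed.pair_table.backend!r}")
    pt = cand.trimmed.pair_table
    core = cand.core
    checks = []
    checks.append(("mfe_interval",
                   mfe_within_pi(reg, len(pt), pt.mfe)))
    hm = hairpin_metrics(pt)
    checks.append(("loop_size", hm.terminal_loop_size <= thresholds.max_loop))
    checks.append(("branches", hm.branch_count <= thresholds.max_branches))
    checks.append(("core_bulges",
                   core.bulge_count <= thresholds.max_core_bulges
                   and core.max_bulge_size <= thresholds.max_core_bulge_size))
    checks.append(("continuous_unpaired",
                   core.max_continuous_unpaired <= thresholds.max_continuous_unpaired))
    checks.append(("core_loop_branch", not core.contains_loop_or_branch))
    checks.append(("core_mismatch_allowance",
                   core.unpaired_count <= thresholds.allowance(core.length_bp)))
    for rule, ok in checks:
        if not ok:
            cand.verdict = f"fail:{rule}"
            return cand.verdict
    cand.verdict = "pass"
    return cand.verdict


def keep_best_per_locus(cands: Iterable[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Deduplicate overlapping candidates on the same EST/strand: the highest
    mature read count wins (ties: leftmost span, then read id)."""
    by_key: dict[tuple, list[PrecursorCandidate]] = {}
    for c in cands:
        by_key.setdefault((c.est_id, c.strand), []).append(c)
    out = []
    for group in by_key.values():
        group.sort(key=lambda c: (c.mature_span[0], c.mature_read_id))
        clusters: list[list[PrecursorCandidate]] = []
        for c in group:
            placed = False
            for cl in clusters:
                if any(c.mature_span[0] < o.mature_span[1] and o.mature_span[0] < c.mature_span[1]
                       for o in cl):
                    cl.append(c)
                    placed = True
                    break
            if not placed:
                clusters.append([c])
        for cl in clusters:
            best = max(cl, key=lambda c: (c.mature_count, -c.mature_span[0], c.mature_read_id))
            out.append(best)
    return out


def shuffle_preserving_composition(sequence: str, seed) -> str:
    """Uniform random permutation of the residues (exact composition kept)."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(sequence))
    return "".join(chars[rng.permutation(len(chars))])


def benchmark(positives: Sequence[tuple[str, tuple[int, int]]], seed: int,
              thresholds: FilterThresholds, reg: MfeRegression,
              temperature: float = 25.0) -> tuple[float, float, pd.DataFrame]:
    """Sensitivity/specificity of the cascade on hairpins vs their shuffles.

    positives: (precursor sequence, mature span) pairs. One composition-
    preserving shuffle per positive serves as its negative; the mature span
    coordinates are reused on the shuffled sequence. Returns (sensitivity,
    specificity, audit table).
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    rows = []
    tp = tn = 0
    rng = np.random.default_rng(seed)
    for idx, (seq, span) in enumerate(positives):
        cand = build_candidate(f"pos{idx}", "+", seq, span, f"mature{idx}", "novel",
                               temperature=temperature)
        verdict = evaluate_candidate(cand, thresholds, reg)
        tp += verdict == "pass"
        rows.append({"id": f"pos{idx}", "kind": "positive", "verdict": verdict})
        shuf = shuffle_preserving_composition(seq, rng.integers(0, 2 ** 31 - 1))
        ncand = build_candidate(f"neg{idx}", "+", shuf, span, f"mature{idx}", "novel",
                                temperature=temperature)
        nverdict = evaluate_candidate(ncand, thresholds, reg)
        tn += nverdict != "pass"
        rows.append({"id": f"neg{idx}", "kind": "negative", "verdict": nverdict})
    n = len(positives)
    return tp / n, tn / n, pd.DataFrame(rows)
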