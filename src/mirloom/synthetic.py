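"""Synthetic data generation: EST collections with implanted miRNA hairpins,
strand-specific tissue read libraries with log-normal abundance structure,
contaminants, decoys and implanted target sites -- with an exact truth table,
so every pipeline stage is testable without downloads.

What the generator emulates: a gel-selected (18-30 nt insert) strand-specific
small RNA protocol over four tissue libraries; hairpin precursors hosted on
non-coding transcripts with the mature on one arm and a 2-nt-overhang star on
the other; degraded-mRNA fragments from coding transcripts; structural-RNA
fragments; contaminant (organellar/viral) fragments; uniform substitution
sequencing errors; a 3' adapter read-through. What it does not emulate:
quality-score profiles, position-dependent error spectra, ligation bias, or
realistic transcriptome redundancy -- conclusions from synthetic recovery
tests are about the pipeline's logic, not about wet-lab behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ESTRecord, ReferenceRecord, ReferenceSet, revcomp

LIBRARIES = ("root", "leaf", "flower", "seed")

_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _balanced_seq(rng: np.random.Generator, n: int, n_gc: int | None = None) -> str:
    """Random sequence with an exact G+C count (default: n // 2).

    Hairpin arms are drawn composition-balanced so that stem stability is a
    tight function of stem length -- mirroring the roughly balanced base
    composition of real plant precursor stems and keeping the MFE-vs-length
    relation narrow enough for interval-based filtering.
    """
    if n_gc is None:
        n_gc = n // 2
    n_gc = max(0, min(n, n_gc))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_gc, replace=False)] = True
    gc = np.array(list("GC"))
    at = np.array(list("AT"))
    out = np.where(flags, gc[rng.integers(0, 2, size=n)], at[rng.integers(0, 2, size=n)])
    return "".join(out)


def _balanced_mature(rng: np.random.Generator, n: int, u_bias: float = 0.8) -> str:
    """A mature miRNA sequence with balanced composition and the usual 5' U
    bias of plant miRNAs."""
    first = "T" if rng.random() < u_bias else str(rng.choice(list("ACG")))
    rest_gc = n // 2 - (0 if first in "AT" else 1)
    return first + _balanced_seq(rng, n - 1, rest_gc)


@dataclass
class SimulationConfig:
    seed: int = 0
    libraries: tuple = LIBRARIES
    n_coding_ests: int = 6
    n_plain_noncoding: int = 4
    n_conserved_mirnas: int = 3
    n_novel_mirnas: int = 2
    n_decoys: int = 2
    n_structural: int = 3
    est_len: tuple = (150, 260)
    # inclusive ranges; the defaults pin the textbook geometry (6 bp of stem
    # padding, 8 nt loop) so that designed hairpins are unambiguous ground
    # truth whose stability is a tight function of length -- widen for
    # stress-testing the structural filters
    arm_pad: tuple = (6, 6)          # extra stem bp on each side of the mature
    loop_len: tuple = (8, 8)
    flank_len: tuple = (15, 40)
    mature_len: tuple = (20, 24)
    # log-normal abundance: exp(N(mu, sigma)) scaled per tissue
    abundance_mu: float = 3.0
    abundance_sigma: float = 1.0
    tissue_boost: float = 20.0       # multiplier in the entity's "home" tissue
    n_degraded_per_est: int = 3
    n_noise_reads: int = 10
    contaminant_fraction: float = 0.05
    substitution_rate: float = 0.0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 36
    min_count: int = 4

    def __post_init__(self) -> None:
        for r in (self.contaminant_fraction, self.substitution_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class ImplantedMiRNA:
    mirna_id: str
    kind: str                  # "conserved" | "novel" | "decoy"
    mature: str
    star: str
    host_est: str
    strand: str
    mature_span: tuple[int, int]   # on the host strand carrying the hairpin
    star_span: tuple[int, int]
    counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class TruthTable:
    mirnas: list = field(default_factory=list)          # ImplantedMiRNA
    target_sites: pd.DataFrame | None = None
    read_counts: pd.DataFrame | None = None             # sequence x library truth
    manifest: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    coding_ests: list
    noncoding_ests: list
    structural_refs: ReferenceSet
    mirna_refs: ReferenceSet
    contaminant_refs: ReferenceSet
    raw_reads: dict                                     # library -> list of read strings
    truth: TruthTable


def make_hairpin_est(
    mature: str,
    rng: np.random.Generator,
    loop_len: int = 8,
    arm_pad: tuple[int, int] = (6, 6),
    flank_len: tuple[int, int] = (20, 20),
    max_tries: int = 40,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Build an EST embedding a perfect hairpin whose 5' arm contains the
    mature; returns (est sequence, mature span, star span), 0-based half-open.

    The 3' arm is the reverse complement of the 5' arm, so the designed stem
    is fully paired; the built-in folder is run to verify every designed pair
    actually forms (random flanks can in principle compete), resampling the
    random parts on failure. The star span carries the canonical 2-nt 3'
    overhangs.
    """
    from .structure import derive_star, fold

    if loop_len < 3:
        raise ValueError("hairpin loop must be at least 3 nt")
    if not 18 <= len(mature) <= 26:
        raise ValueError("mature length out of supported range")
    pad5, pad3 = arm_pad
    if (pad5 + len(mature) + pad3) % 2:
        pad3 += 1  # even stem length so the arm can hold exactly half G+C
    mature_gc = sum(1 for b in mature if b in "GCgc")
    arm_len = pad5 + len(mature) + pad3
    pads_gc = max(0, min(pad5 + pad3, round(arm_len / 2) - mature_gc))
    gc5 = round(pads_gc * pad5 / max(pad5 + pad3, 1))

    def unpairable(n: int) -> str:
        # {A, C} admits no legal pair with itself: used for the loop and the
        # 10-nt flank buffers so neither can compete with the designed stem
        return "".join(np.array(list("AC"))[rng.integers(0, 2, size=n)])

    def flank(n: int, buffer_first: bool) -> str:
        buf = unpairable(min(n, 10))
        rest = _rand_seq(rng, max(0, n - 10))
        return (buf + rest) if buffer_first else (rest + buf)

    for _ in range(max_tries):
        arm5 = _balanced_seq(rng, pad5, gc5) + mature + _balanced_seq(rng, pad3, pads_gc - gc5)
        loop = unpairable(loop_len)
        hairpin = arm5 + loop + revcomp(arm5)
        f5 = flank(flank_len[0], buffer_first=False)
        f3 = flank(flank_len[1], buffer_first=True)
        est = f5 + hairpin + f3
        m_start = len(f5) + pad5
        m_span = (m_start, m_start + len(mature))
        # verify the designed stem forms under the builtin model
        pt = fold(est)
        h_start = len(f5)
        n_arm = len(arm5)
        L = len(est)
        designed = all(
            pt.partner[h_start + k] == h_start + 2 * n_arm + loop_len - 1 - k
            for k in range(n_arm)
        )
        if not designed:
            continue
        duplex = derive_star(pt, m_span)
        return est, m_span, duplex.star
    raise RuntimeError("could not realise the designed hairpin; relax the geometry")


def _sample_counts(rng: np.random.Generator, cfg: SimulationConfig, home: str,
                   floor: int) -> dict[str, int]:
    out = {}
    for lib in cfg.libraries:
        lam = np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sigma))
        if lib == home:
            lam *= cfg.tissue_boost
        out[lib] = max(int(rng.poisson(lam)), floor if lib == home else 0)
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != c]))
    return "".join(chars)


def simulate(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full dataset and its truth table (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)
    coding = [ESTRecord(f"CEST{i:04d}", _rand_seq(rng, int(rng.integers(*cfg.est_len))),
                        "protein_coding") for i in range(cfg.n_coding_ests)]

    noncoding: list[ESTRecord] = []
    implanted: list[ImplantedMiRNA] = []
    mirna_refs: list[ReferenceRecord] = []

    def implant(kind: str, idx: int) -> None:
        mlen = int(rng.integers(cfg.mature_len[0], cfg.mature_len[1] + 1))
        mature = _balanced_mature(rng, mlen)
        est, m_span, s_span = make_hairpin_est(
            mature, rng,
            loop_len=int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1)),
            arm_pad=(int(rng.integers(cfg.arm_pad[0], cfg.arm_pad[1] + 1)),
                     int(rng.integers(cfg.arm_pad[0], cfg.arm_pad[1] + 1))),
            flank_len=(int(rng.integers(*cfg.flank_len)), int(rng.integers(*cfg.flank_len))),
        )
        strand = "+" if rng.random() < 0.5 else "-"
        est_id = f"NEST{len(noncoding):04d}"
        stored = est if strand == "+" else revcomp(est)
        noncoding.append(ESTRecord(est_id, stored, "noncoding"))
        star = est[s_span[0]:s_span[1]]
        home = str(rng.choice(list(cfg.libraries)))
        mid = f"{kind[:3]}-{idx}"
        rec = ImplantedMiRNA(
            mirna_id=mid, kind=kind, mature=mature, star=star, host_est=est_id,
            strand=strand, mature_span=m_span, star_span=s_span,
            counts=_sample_counts(rng, cfg, home, cfg.min_count),
            star_counts=_sample_counts(rng, cfg, home, cfg.min_count),
        )
        implanted.append(rec)
        if kind == "conserved":
            mirna_refs.append(ReferenceRecord(f"pap-miR{900 + idx}", f"miR{900 + idx}", mature))

    for i in range(cfg.n_conserved_mirnas):
        implant("conserved", i)
    for i in range(cfg.n_novel_mirnas):
        implant("novel", i)

    # decoys: composition-preserving shuffles of hairpin hosts, plus a fake
    # "mature" read drawn from the shuffled sequence
    decoys: list[ImplantedMiRNA] = []
    for i in range(cfg.n_decoys):
        src = implanted[int(rng.integers(0, len(implanted)))]
        host = [e for e in noncoding if e.id == src.host_est][0]
        seq = host.sequence if src.strand == "+" else revcomp(host.sequence)
        shuf = "".join(np.array(list(seq))[rng.permutation(len(seq))])
        est_id = f"NEST{len(noncoding):04d}"
        noncoding.append(ESTRecord(est_id, shuf, "noncoding"))
        pos = int(rng.integers(0, len(shuf) - 21))
        decoys.append(ImplantedMiRNA(
            mirna_id=f"dec-{i}", kind="decoy", mature=shuf[pos:pos + 21], star="",
            host_est=est_id, strand="+", mature_span=(pos, pos + 21), star_span=(0, 0),
            counts=_sample_counts(rng, cfg, str(rng.choice(list(cfg.libraries))), cfg.min_count),
        ))
    implanted.extend(decoys)

    for i in range(cfg.n_plain_noncoding):
        noncoding.append(ESTRecord(f"NEST{len(noncoding):04d}",
                                   _rand_seq(rng, int(rng.integers(*cfg.est_len))), "noncoding"))

    families = ["rRNA", "tRNA", "snRNA", "snoRNA", "other_sRNA"]
    structural = ReferenceSet("structural_rna", [
        ReferenceRecord(f"struct{i}", families[i % len(families)], _rand_seq(rng, 120))
        for i in range(cfg.n_structural)
    ])
    contaminant = ReferenceSet("contaminant", [
        ReferenceRecord("chloroplast", "", _rand_seq(rng, 1500)),
    ])

    # ----- reads -----
    reads: dict[str, list[str]] = {lib: [] for lib in cfg.libraries}
    truth_rows = []

    def emit(seq: str, counts: dict[str, int], source: str) -> None:
        insert = seq
        for lib, n in counts.items():
            for _ in range(n):
                read = _mutate(rng, insert, cfg.substitution_rate)
                read = (read + cfg.adapter)[:cfg.read_length]
                reads[lib].append(read)
        truth_rows.append({"sequence": seq, "source": source, **counts})

    for m in implanted:
        emit(m.mature, m.counts, f"{m.kind}:{m.mirna_id}")
        if m.kind != "decoy":
            emit(m.star, m.star_counts, f"star:{m.mirna_id}")

    for est in coding:
        for _ in range(cfg.n_degraded_per_est):
            ln = int(rng.integers(18, 29))
            pos = int(rng.integers(0, len(est.sequence) - ln))
            frag = est.sequence[pos:pos + ln]
            emit(frag, _sample_counts(rng, cfg, str(rng.choice(list(cfg.libraries))), cfg.min_count),
                 f"degraded:{est.id}")

    for rec in structural:
        ln = int(rng.integers(19, 26))
        pos = int(rng.integers(0, len(rec.sequence) - ln))
        emit(rec.sequence[pos:pos + ln],
             _sample_counts(rng, cfg, str(rng.choice(list(cfg.libraries))), cfg.min_count),
             f"structural:{rec.id}")

    n_entities = len(truth_rows)
    n_contam = int(round(cfg.contaminant_fraction * n_entities)) or (
        1 if cfg.contaminant_fraction > 0 else 0)
    for i in range(n_contam):
        src = contaminant.records[0]
        ln = int(rng.integers(19, 26))
        pos = int(rng.integers(0, len(src.sequence) - ln))
        emit(src.sequence[pos:pos + ln],
             _sample_counts(rng, cfg, str(rng.choice(list(cfg.libraries))), cfg.min_count),
             f"contaminant:{src.id}")

    for i in range(cfg.n_noise_reads):
        emit(_rand_seq(rng, int(rng.integers(18, 29))),
             {lib: (cfg.min_count if lib == cfg.libraries[i % len(cfg.libraries)] else 0)
              for lib in cfg.libraries},
             f"noise:{i}")

    truth = TruthTable(
        mirnas=implanted,
        read_counts=pd.DataFrame(truth_rows),
        manifest={"seed": cfg.seed, "libraries": list(cfg.libraries),
                  "substitution_rate": cfg.substitution_rate,
                  "adapter": cfg.adapter},
    )
    mirna_refset = ReferenceSet("known_mirna", mirna_refs)
    return SyntheticDataset(coding_ests=coding, noncoding_ests=noncoding,
                            structural_refs=structural, mirna_refs=mirna_refset,
                            contaminant_refs=contaminant, raw_reads=reads, truth=truth)


def training_hairpins(n: int, seed: int, loop_len: tuple = (8, 8),
                      arm_pad: tuple = (6, 6), mature_len: tuple = (20, 24),
                      flank: int = 0) -> list[tuple[str, tuple[int, int]]]:
    """n designed hairpins with their mature spans: the training set for the
    MFE-vs-length regression and the positive set for the shuffle benchmark.
    Lengths vary through the mature length; geometry defaults to the textbook
    shape (see SimulationConfig) so designed hairpins are clean positives."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        mlen = int(rng.integers(mature_len[0], mature_len[1] + 1))
        mature = _balanced_mature(rng, mlen, u_bias=1.0)
        est, m_span, _ = make_hairpin_est(
            mature, rng,
            loop_len=int(rng.integers(loop_len[0], loop_len[1] + 1)),
            arm_pad=(int(rng.integers(arm_pad[0], arm_pad[1] + 1)),
                     int(rng.integers(arm_pad[0], arm_pad[1] + 1))),
            flank_len=(flank, flank) if flank else (int(rng.integers(10, 20)),
                                                    int(rng.integers(10, 20))),
        )
        out.append((est, m_span))
    return out


def mfe_training_table(n: int, seed: int) -> list[tuple[int, float]]:
    """(length, MFE) pairs from trimmed, refolded designed hairpins, folded
    with the builtin backend -- the packaged stand-in for an experimentally
    validated precursor table (synthetic; see docstring)."""
    from .precursor import build_candidate

    out = []
    for idx, (est, span) in enumerate(training_hairpins(n, seed)):
        cand = build_candidate(f"train{idx}", "+", est, span, f"t{idx}", "novel")
        if cand.trimmed is not None:
            out.append((len(cand.trimmed.sequence), cand.trimmed.pair_table.mfe))
    return out
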