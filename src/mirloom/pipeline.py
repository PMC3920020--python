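"""End-to-end orchestration: preprocess -> annotate -> precursors -> novel
-> targets -> expression, with per-stage TSV outputs and an attrition table.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .annotate import aggregate_families, category_table, classify_reads
from .discovery import call_novel_mirnas
from .expression import (fold_change, profile_table, profiles_from_family_counts, spm)
from .model import AlignParams, UniqueRead
from .precursor import (FilterThresholds, evaluate_candidate, fit_mfe_regression,
                        generate_candidates, keep_best_per_locus)
from .preprocess import PreprocessConfig, preprocess_libraries
from .targets import complementarity_scan


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Validated bundle of inputs and thresholds for a full run.

    The defaults are the study's printed values: 18-30 nt length window,
    total-count >= 4, up to 3 discrepancies against structural RNA, up to 3
    mismatches against known matures, the 8-rule precursor cascade, exact
    star matching, 20-24 nt novel matures, fold at 25 degC.
    """

    raw_reads: dict                 # library -> list of read strings
    coding_ests: list
    noncoding_ests: list
    structural_refs: object
    mirna_refs: object
    contaminant_refs: object | None = None
    preprocess: PreprocessConfig = None
    align: AlignParams = None
    thresholds: FilterThresholds = None
    mfe_training: list = None       # (length, mfe) pairs, builtin backend
    temperature: float = 25.0
    seed: int = 0
    out_dir: str | None = None
    run_targets: bool = True

    def __post_init__(self) -> None:
        if self.preprocess is None:
            self.preprocess = PreprocessConfig(contaminant_refs=self.contaminant_refs)
        if self.align is None:
            self.align = AlignParams()
        if self.thresholds is None:
            self.thresholds = FilterThresholds()
        if not self.raw_reads:
            raise ValueError("no read libraries supplied")
        for name in ("coding_ests", "noncoding_ests", "structural_refs", "mirna_refs"):
            if getattr(self, name) is None:
                raise ValueError(f"missing input: {name}")
        if self.mfe_training is None or len(self.mfe_training) < 3:
            raise ValueError("mfe_training needs at least 3 (length, mfe) pairs")


@dataclass
class RunResult:
    reads: list
    library_totals: dict
    annotations: list
    family_counts: list
    conserved_candidates: list
    novel_mirnas: list
    target_sites: list
    profiles: pd.DataFrame
    attrition: pd.DataFrame
    category_matrix: pd.DataFrame


def run_pipeline(cfg: RunConfig) -> RunResult:
    thresholds, reg = cfg.thresholds, fit_mfe_regression(cfg.mfe_training)

    try:
        pp = preprocess_libraries(cfg.raw_reads, cfg.preprocess)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise PipelineError("preprocess", e) from e

    try:
        records = classify_reads(pp.reads, cfg.coding_ests, cfg.noncoding_ests,
                                 cfg.structural_refs, cfg.mirna_refs, cfg.align)
        fams = aggregate_families(records, pp.reads)
        cat = category_table(records, pp.reads)
    except Exception as e:
        raise PipelineError("annotate", e) from e

    by_id = {r.id: r for r in pp.reads}
    try:
        mirna_recs = [r for r in records if r.category == "miRNA"]
        mature_set = [(r.read_id, by_id[r.read_id].sequence) for r in mirna_recs]
        counts = {r.read_id: by_id[r.read_id].total_count for r in mirna_recs}
        families = {r.read_id: r.family for r in mirna_recs}
        cands = generate_candidates(mature_set, cfg.noncoding_ests, "conserved_match",
                                    mature_counts=counts, families=families,
                                    temperature=cfg.temperature)
        cands = keep_best_per_locus(cands)
        for c in cands:
            evaluate_candidate(c, thresholds, reg)
    except Exception as e:
        raise PipelineError("precursors", e) from e

    try:
        unmatched = [by_id[r.read_id] for r in records
                     if r.category in ("unmatched", "noncoding_est")]
        novel = call_novel_mirnas(unmatched, cfg.noncoding_ests, thresholds, reg,
                                  all_reads=pp.reads, temperature=cfg.temperature)
    except Exception as e:
        raise PipelineError("novel", e) from e

    sites = []
    if cfg.run_targets:
        try:
            seen = set()
            for rid, seq in mature_set:
                if seq in seen:
                    continue
                seen.add(seq)
                sites.extend(complementarity_scan(families.get(rid, rid), seq,
                                                  cfg.coding_ests))
            for n in novel:
                mseq = n.mature_sequence.replace("U", "T")
                if mseq not in seen:
                    seen.add(mseq)
                    sites.extend(complementarity_scan(n.mirna_id, mseq, cfg.coding_ests))
        except Exception as e:
            raise PipelineError("targets", e) from e

    try:
        profiles = profiles_from_family_counts(fams, pp.library_totals)
        libs = list(cfg.raw_reads)
        prof_df = profile_table(profiles, libs)
    except Exception as e:
        raise PipelineError("expression", e) from e

    attrition = pd.DataFrame(
        [{"step": step, **totals} for step, totals in pp.attrition])

    result = RunResult(reads=pp.reads, library_totals=pp.library_totals,
                       annotations=records, family_counts=fams,
                       conserved_candidates=cands, novel_mirnas=novel,
                       target_sites=sites, profiles=prof_df, attrition=attrition,
                       category_matrix=cat)
    if cfg.out_dir:
        write_report_bundle(result, cfg)
    return result


def write_report_bundle(res: RunResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_count_matrix(res.reads, out / "unique_reads.tsv", libraries=list(cfg.raw_reads))
    res.attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
    res.category_matrix.to_csv(out / "category_matrix.tsv", sep="\t", index=False)
    res.profiles.to_csv(out / "family_profiles.tsv", sep="\t", index=False)

    ann = pd.DataFrame([
        {"read_id": r.read_id, "category": r.category, "family": r.family or "",
         "ref_id": r.evidence.ref_id if r.evidence else "",
         "strand": r.evidence.strand if r.evidence else "",
         "position": r.evidence.position + 1 if r.evidence else "",
         "mismatches": r.evidence.mismatches if r.evidence else "",
         "gaps": r.evidence.gaps if r.evidence else ""}
        for r in res.annotations])
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False)

    prec = pd.DataFrame([
        {"family": c.family or "", "precursor_id": c.est_id, "strand": c.strand,
         "length": c.trimmed_length,
         "mature_read": c.mature_read_id, "mfe": c.mfe if c.mfe is not None else "",
         "verdict": c.verdict}
        for c in res.conserved_candidates])
    prec.to_csv(out / "conserved_precursors.tsv", sep="\t", index=False)

    nov = pd.DataFrame([
        {"mir_id": n.mirna_id, "read_id": n.mature_read_id, "size": len(n.mature_sequence),
         "mature_sequence": n.mature_sequence, "precursor_source": n.precursor.est_id,
         "precursor_length": n.precursor.trimmed_length,
         "mfe": n.precursor.mfe, "star_read_id": n.star_read_id}
        for n in res.novel_mirnas])
    nov.to_csv(out / "novel_mirnas.tsv", sep="\t", index=False)

    tgt = pd.DataFrame([
        {"mirna": s.mirna_id, "transcript_id": s.transcript_id,
         "start": s.span_1based[0], "end": s.span_1based[1],
         "alignment_length": s.alignment_length, "mismatches": s.mismatches}
        for s in res.target_sites])
    tgt.to_csv(out / "target_sites.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "temperature": cfg.temperature,
        "libraries": list(cfg.raw_reads),
        "library_totals": res.library_totals,
        "preprocess": {k: v for k, v in asdict(cfg.preprocess).items()
                       if k != "contaminant_refs"},
        "align": asdict(cfg.align),
        "thresholds": {k: v for k, v in asdict(cfg.thresholds).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
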