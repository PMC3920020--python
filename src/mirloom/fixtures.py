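"""Packaged reference tables from the published *Phalaenopsis aphrodite*
small RNA transcriptome survey (four tissue libraries: root, leaf, flower,
seed). These are machine-readable transcriptions of the study's summary
tables; they let the arithmetic layers (shares, SPM, summaries) be exercised
and checked without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LIBRARIES = ("root", "leaf", "flower", "seed")


def _load(name: str) -> pd.DataFrame:
    with resources.files("mirloom.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def processing_summary() -> pd.DataFrame:
    """Read-attrition accounting: unique/total reads per processing step and
    library (the 'after_contaminant_removal' totals are the RPM denominators)."""
    return _load("study_processing_summary.tsv")


def category_counts() -> pd.DataFrame:
    """Unique/total read counts per annotation category and library."""
    return _load("study_category_counts.tsv")


def family_rpm() -> pd.DataFrame:
    """Top-30 miRNA family expression (RPM per tissue); ``high_spm_tissue``
    marks the tissue the study flagged as specific (SPM > 0.9), if any."""
    df = _load("study_family_rpm.tsv")
    df["high_spm_tissue"] = df["high_spm_tissue"].fillna("")
    return df


def conserved_precursors() -> pd.DataFrame:
    """The 74 predicted conserved-miRNA precursors: family, host transcript,
    length, 1-based position span (reverse spans = minus strand), MFE
    (kcal/mol, Mfold at 25 degC) and the mature source (P = this study's
    annotated miRNAs, M = public mature miRNA registry)."""
    return _load("study_conserved_precursors.tsv")


def novel_mirnas() -> pd.DataFrame:
    """The 24 novel mature miRNA records (23 distinct reads from 17
    precursors), with star-supported mature sequences and targets."""
    df = _load("study_novel_mirnas.tsv")
    df["targets"] = df["targets"].fillna("")
    return df


def library_totals() -> dict[str, int]:
    """Post-filter total reads per library (RPM denominators)."""
    df = processing_summary()
    final = df[df["step"] == "after_contaminant_removal"]
    return {r["library"]: int(r["total_reads"]) for _, r in final.iterrows()
            if r["library"] != "total"}
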