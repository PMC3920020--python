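# mirloom

Reference-genome-free small RNA analysis for non-model organisms: read
collapsing and filtering, an annotation cascade over EST and structural-RNA
references, stem-loop miRNA precursor prediction with structural filters and
an MFE-vs-length prediction interval, novel miRNA discovery with mandatory
miRNA\* duplex evidence, complementarity-based target prediction, and
RPM/SPM tissue-specificity expression profiling.

The package is aimed at transcriptomics of species without a sequenced
genome — the motivating case is the orchid *Phalaenopsis aphrodite*, where
~230k EST/transcript sequences replace a reference genome for mapping
four tissue small-RNA libraries (root, leaf, flower, seed).

## The method in brief

1. **Collapse & filter.** Identical reads collapse into unique reads with
   per-library counts; adapter/poly-N trimming, an 18–30 nt window, a
   total-count ≥ 4 filter and contaminant removal (exact full-length match,
   either strand) clean the set.
2. **Annotate.** A fixed cascade assigns one category per read: degraded
   mRNA (sense-perfect on coding ESTs) → structural RNA (≤ 3 gaps+mismatches)
   → known miRNA (≤ 3 substitutions, family-pooled) → non-coding EST →
   unmatched.
3. **Predict precursors.** Matures are placed on both strands of non-coding
   ESTs; each locus is folded, the miRNA\* span derived with 2-nt 3′
   overhangs, trimmed to the duplex ± 10 nt, refolded, and passed through
   ordered filters: mature in the stem; MFE inside the 95 % prediction
   interval of MFE ~ length,

       MFE ∈ ŷ(L) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (L − L̄)²/Sxx);

   terminal loop ≤ 15 nt; branches ≤ 6; core bulges ≤ 1 (size ≤ 2);
   continuous unpaired ≤ 4; no loop/branch in the core; unpaired residues
   within a core-length-graded allowance (≤17 bp: 1; 18: 2; 19: 3; 20: 4;
   >20: 5).
4. **Discover novel miRNAs.** Unannotated reads placed perfectly on
   non-coding ESTs run the same cascade, and a call requires the miRNA\*
   sequence itself in the libraries (Meyers-style duplex evidence).
5. **Predict targets.** Ungapped antisense scan, Watson–Crick only (G:U is
   a mismatch), covering miRNA positions 2–12, aligned > 16 nt, ≤ 3
   mismatches; plus homology transfer of known model-organism targets; dual
   non-overlapping sites flag TAS-like transcripts.
6. **Profile expression.** RPM = count/total × 10⁶; SPM_i = x_i/‖x‖₂
   (cosine to the one-tissue vector, 1 = perfectly specific); fold-change ≥ 4
   selection and Euclidean/centroid-linkage clustering.

A synthetic-data generator (`mirloom.synthetic`) builds EST collections with
implanted hairpins, star reads, contaminants, decoys and a full truth table,
so every stage is testable without downloads; transcriptions of the
published survey's summary tables ship in `mirloom.fixtures`.

## Worked example

```bash
python examples/07_study_tables.py
```

prints, from the packaged study tables:

```
miRNA share of all small RNA reads (%): {'root': 10.5, 'leaf': 26.0, 'flower': 12.7, 'seed': 14.8}
miR159 share of all miRNA reads (%): {'root': 38.6, 'leaf': 44.2, 'flower': 66.0, 'seed': 21.5}
conserved precursors: n=74, length 55.0-293.0 nt, MFE -198.14 to -12.72 kcal/mol
novel precursors: mean length 128 nt; 19/23 matures start with U
SPM(miR398) in leaf: 0.9832
SPM(miR2911) in root: 0.9502
```

— the miRNA fraction of each library, miR159's dominance of the miRNA pool,
the precursor length/energy ranges, the 5′-uridine bias of novel matures,
and the two SPM values above the 0.9 threshold that mark miR398 as
leaf-specific and miR2911 as root-specific.

The other examples each exercise one capability end to end
(`01_preprocess_reads.py` … `06_target_prediction.py`), and a thin CLI wraps
the same functions:

```bash
mirloom run --seed 3 -o out/        # simulate + full pipeline
mirloom benchmark --n 20 --seed 1   # shuffle sensitivity/specificity
mirloom preprocess --contaminants contam.fasta -o counts.tsv root.fastq ...
```

## Layout

```
src/mirloom/
  model.py       core types, read collapsing
  io.py          FASTA/FASTQ/TSV readers and writers
  preprocess.py  trimming and filtering
  annotate.py    classification cascade, k-edit search
  fold.py        built-in stacking-model folding engine
  structure.py   pair tables, hairpin metrics, star derivation, trimming
  precursor.py   MFE regression/interval, filter cascade, shuffle benchmark
  discovery.py   novel miRNA calling with star evidence
  targets.py     complementarity scan, homology transfer, TAS-like loci
  expression.py  RPM, SPM, fold-change, centroid clustering
  synthetic.py   data generator with truth tables
  fixtures.py    packaged published study tables
  pipeline.py    end-to-end orchestration
  cli.py         thin command-line layer
```

See `docs/methods.md` for the models, parameter defaults and their
rationale, numerical choices, and known limitations.
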