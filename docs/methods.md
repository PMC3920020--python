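# Methods

`mirloom` reimplements a reference-genome-free small RNA analysis pipeline of
the kind used for non-model plants such as *Phalaenopsis aphrodite*, where
EST/transcript collections stand in for a genome. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Read processing

Reads are collapsed into *unique reads* only when completely identical in
length and sequence; a single-nucleotide difference keeps reads distinct, so
collapsing never erases sequence heterogeneity. Preprocessing applies, in
order: exact-match 3' adapter trimming (longest read suffix equal to an
adapter prefix, minimum overlap 6 nt — the exact-overlap rule is this
package's own deterministic definition), exclusion of reads containing N
(masked low-quality segments) or consisting of a single repeated base,
trimming of trailing mono-nucleotide runs longer than 8 nt, an 18–30 nt
length window (mirroring gel size selection), removal of unique reads seen
fewer than 4 times in total across libraries (low-coverage reads are
overwhelmingly sequencing errors, and without a reference genome no
error-correction by alignment is possible), and contaminant removal by exact
full-length substring match against either strand of contaminant references
(the contract equivalent of parsing 100 %-identity full-span hits out of a
BLAST report; organellar and viral reads arise from both strands, so this
step is deliberately not strand-specific).

## Annotation cascade

Each surviving read receives exactly one category, in fixed precedence:
sense-strand perfect hits on protein-coding ESTs (degraded mRNA — the
protocol is strand-specific, so antisense hits do not count), structural
RNA (rRNA/tRNA/snRNA/snoRNA/other) within 3 discrepancies (gaps plus
mismatches, semi-global), known mature miRNAs within 3 substitutions
(ungapped), then non-coding-EST-only reads, then unmatched. Perfect
non-coding-EST placements are recorded on both strands for every read and
carried as evidence. The miRNA mismatch cap is configurable
(`AlignParams.max_mismatches`, default 3): published descriptions of this
style of screen are ambiguous between ≤2 and ≤3, so the bound is explicit
rather than inferred. Family labels strip the species prefix and
letter/arm suffixes (ath-miR156a-5p → miR156); pooling of near-identical
families (156/157, 159/319) is left to an explicit user merge map.

The gapped search is backed by edlib (infix alignment); an independent
full-DP oracle in the test suite checks its edit counts. Ties across
references at equal edit count are broken by fewest mismatches, then
reference order, and affect the recorded evidence only, never the category.

## Secondary structure

The built-in folder maximises a simple additive score over nested
structures: pair scores G:C = 3, A:U = 2, G:U = 1, a stacking bonus of 1 per
contiguous pair, hairpin loops of at least 3 nt, no pseudoknots. It is a
deterministic O(n³) dynamic programme with fixed tie-breaking; for
sequences ≤ 16 nt the optimum is verified against exhaustive enumeration of
all legal structures. Its "MFE" is the negated score in arbitrary
kcal/mol-like units and is **not comparable** to Mfold or ViennaRNA
energies; every `PairTable` carries a backend tag and the MFE filter
refuses to mix backends. Externally computed structures (any folding
program, including Mfold/RNAfold at 25 °C) enter through Vienna-style
dot-bracket files; the fold temperature is metadata for the built-in model.

Structural vocabulary is pinned down because published usage conflates
terms: a *mismatch* is a symmetric 1:1 internal loop; a *bulge* is an
unpaired run on one strand (an asymmetric internal loop counts its
symmetric part as mismatches and its excess as a bulge on the longer side);
*branches* are helices emanating from multiloops beyond the entering helix
(the exterior loop counts when it holds more than one helix); the *terminal
loop* is the hairpin loop reached from the outermost pair taking the
pair-richest branch at any multiloop.

The miRNA* span is derived from the pair table as partner(mature_end − 2)
to partner(mature_start) + 2 — the canonical 2-nt 3' overhang on both
strands — with unpaired anchors resolved by the nearest paired neighbour
with positional compensation. Precursors are trimmed to the outermost
mature/miRNA* base pair ± 10 nt, clamped at the sequence ends, and refolded
with the built-in engine before filtering.

## Precursor filter cascade

Ordered checks, first failure recorded: (1) mature in the stem, not the
loop; (2) trimmed-hairpin MFE inside a two-sided 95 % prediction interval
from an OLS regression of MFE on length (sequences of different lengths
have incomparable energies, so a single absolute cutoff would be wrong);
(3) terminal loop ≤ 15 nt; (4) branches ≤ 6; (5) core bulges ≤ 1 of size
≤ 2; (6) longest continuous unpaired run of core residues ≤ 4; (7) no
loop/branch inside the core; (8) total unpaired core residues within a
length-graded allowance (≤17 bp: 1; 18: 2; 19: 3; 20: 4; >20: 5). Unpaired
core residues are counted once each, whether they sit in a mismatch or a
bulge. All thresholds are configurable; the defaults are the conventional
printed values. The prediction interval is
ŷ(L) ± t(0.975, n−2)·s·√(1 + 1/n + (L−L̄)²/Sxx); a degenerate zero residual
is widened by a small epsilon (1e−6), and a one-sided variant (reject only
insufficiently stable structures) is available but off by default.

Candidates are generated for every qualifying (mature, EST, strand)
placement — perfect matches for conserved and novel modes, ≤ 3 edits for
the registry-screen mode — folding both EST strands. Overlapping
placements on one locus deduplicate to the most abundant mature read, the
standard "the most sequenced arm is the mature" convention.

The shuffle benchmark pairs each positive hairpin with one
composition-preserving random permutation (seeded, audited) and reports
sensitivity (accepted positives) and specificity (rejected shuffles).
Reproducing the published Arabidopsis benchmark numbers (85 % / 100 %)
would require the specific historical miRBase release and Mfold energies;
the packaged benchmark instead establishes the same property on generator
truth, where it is exactly checkable.

## Novel miRNA discovery

Unmatched and non-coding-EST reads of mature length (20–24 nt) are placed
perfectly on non-coding ESTs, run through the full cascade, and — the
decisive filter — the derived miRNA* sequence must itself occur in the
post-filter read set (exact match by default; a ±shift tolerance is
config). Hairpin-shaped loci are ubiquitous; hairpins whose opposite arm
was independently sequenced with a 2-nt-overhang geometry are not, which is
what controls the false-positive rate. Calls are named sequentially with a
5p/3p arm suffix; the arm is the side of the terminal loop holding the
mature. Whether the star must itself pass the low-count filter is not
standardised; here it must merely be present in the post-filter set.

## Target prediction

Complementarity scan: ungapped antisense alignment at every offset of the
transcript sense strand (coding ESTs are oriented; miRNAs act on mRNA).
Only Watson–Crick pairs count — G:U is a mismatch here, by design in
contrast to folding. A site must cover miRNA positions 2–12 (1-based from
the 5' end), align > 16 nt (≥ 17 contiguous positions), carry ≤ 3
mismatches, and begin and end on a match (a local ungapped alignment never
extends past a terminal mismatch). Overlapping qualifying windows merge to
the best (fewest mismatches, then longest, then leftmost). Mismatches
inside 2–12 are not separately restricted by default (`max_mismatches_seed`
optionally tightens this). The homology route joins best protein-level
hits (e-value ≤ 1e−30) against a table of known model-organism targets,
restricted to families seen in the libraries; both routes merge keyed by
(family, transcript) with method flags. Transcripts carrying ≥ 2
non-overlapping sites for one miRNA are flagged as TAS-like loci.

## Expression

RPM = count / library total × 10⁶ over post-filter totals. Family profiles
sum all reads annotated to a family per library. SPM_i = x_i / ‖x‖₂, the
cosine between the profile and the idealised one-tissue vector — in [0, 1],
scale-invariant, 1 exactly for single-tissue expression; the squared
variant x_i²/‖x‖₂² is available (`variant="squared"`), and both agree on
every > 0.9 specificity flag in the packaged study table, so the choice
cannot be settled from the printed data. Fold-change selection keeps
profiles with max/min RPM ≥ 4.0 (inclusive), zeros padded with a 0.01-RPM
pseudo-count (the same pseudo-count guards the log₂ transform). Clustering
is agglomerative with Euclidean distance and centroid linkage
(scipy-backed, brute-force-verified); dendrograms export to Newick.

## Synthetic data

The generator emulates a four-tissue, strand-specific, gel-selected
(18–30 nt) small RNA experiment: non-coding ESTs hosting designed hairpins
(mature on one arm, exact-overhang star on the other, on either strand),
degraded coding-EST fragments, structural-RNA and contaminant fragments,
random noise, a 3' adapter read-through to a fixed read length, uniform
substitution errors, and per-entity log-normal abundance with a ×20 boost
in a home tissue (chosen to produce the several-orders-of-magnitude RPM
ranges real libraries show). Every emitted read is recorded in a truth
table; seeds are mandatory and echoed into the manifest.

Designed hairpins default to a fixed textbook geometry: 6 bp of stem
padding on each side of the mature (arm length forced even), an 8-nt loop
drawn from {A, C} (which cannot base-pair), composition-balanced arms
(exactly half G+C), and 10-nt {A, C} buffers flanking the hairpin. Under
the built-in energy model this makes stem stability an exactly linear
function of trimmed length, so a prediction interval trained on generated
hairpins provably contains every generated hairpin while shuffles fall far
outside — designed positives are unambiguous ground truth. The geometry
(loop size, padding, composition) is configurable for stress-testing the
structural filters; the guarantee then weakens to the usual ~95 % coverage.
The generator does not model quality-score profiles, position-dependent
error spectra, ligation bias, paralogous families, or realistic
transcriptome redundancy: passing recovery tests certifies the pipeline's
logic (bookkeeping, strand handling, filter arithmetic, star matching), not
wet-lab performance on real libraries.

## Packaged study tables

Machine-readable transcriptions of the published survey's summary tables
(processing attrition, category counts, top-30 family RPM with specificity
flags, 74 conserved precursors, 24 novel miRNA records) ship with the
package and drive the desk-arithmetic tests and `scripts/acceptance.py`.
Two printed values do not reproduce exactly from their own printed inputs:
the precursor table's stated mean length/MFE (recompute to 121.95 nt /
−56.34 vs printed 123 / −58.65) and the miR159 seed share (recomputes to
21.5 % vs printed 21.6 %); tests assert the reproducible ranges and allow
0.1 percentage point on the share.

## Problem sizes

Default simulations use 6 coding ESTs, ~11 non-coding ESTs (3 conserved +
2 novel implants, 2 decoys, 4 plain), 3 structural references and a 1.5-kb
contaminant, yielding a few thousand reads per library — sized so a full
pipeline run takes seconds and the 20-seed recovery suite stays
comfortably inside a normal CI budget while still exercising every code
path. The built-in folder is O(n³); synthetic ESTs are kept ≤ ~260 nt.
Larger inputs work but fold time grows accordingly (an external folding
program via the dot-bracket adapter is the practical route for long
transcripts).
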