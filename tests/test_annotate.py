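"""Classification cascade, k-edit search vs a full-DP oracle, family rules."""

import numpy as np
import pytest

from mirloom.annotate import (classify_reads, match_sense_perfect, match_with_edits,
                              mirna_family, aggregate_families)
from mirloom.model import (AlignParams, ESTRecord, ReferenceRecord, ReferenceSet,
                           UniqueRead, revcomp)


def dp_semiglobal(read, ref):
    """Oracle: full dynamic-programming edit distance of the read against
    every substring of ref (free start/end on ref), both strands."""
    best = None
    for target in (ref, revcomp(ref)):
        n, m = len(read), len(target)
        prev = [0] * (m + 1)
        for i in range(1, n + 1):
            cur = [i] + [0] * m
            for j in range(1, m + 1):
                cur[j] = min(prev[j - 1] + (read[i - 1] != target[j - 1]),
                             prev[j] + 1, cur[j - 1] + 1)
            prev = cur
        d = min(prev)
        best = d if best is None else min(best, d)
    return best


class TestMatchWithEdits:
    def test_exact_substring_zero_edits(self):
        h = match_with_edits("ACGTACGT", "TTTACGTACGTTTT", 3)
        assert h is not None and h.mismatches + h.gaps == 0

    def test_three_substitutions_within_cap(self):
        ref = "TTTT" + "ACGTACGTACGTACGTACGTA" + "TTTT"
        read = "AGGTACGAACGTACGTACGTC"  # 3 substitutions
        h = match_with_edits(read, ref, 3, gapped=False)
        assert h is not None and h.mismatches == 3 and h.gaps == 0

    def test_beyond_edit_cap_rejected(self):
        ref = "TTTT" + "ACGTACGTACGTACGTACGTA" + "TTTT"
        read = "GCGCGCGCGCGCGCGCGCGCG"
        assert dp_semiglobal(read, ref) > 3  # oracle confirms distance > cap
        assert match_with_edits(read, ref, 3) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_edit_distance_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        ref = "".join(bases[rng.integers(0, 4, 60)])
        read = "".join(bases[rng.integers(0, 4, 20)])
        oracle = dp_semiglobal(read, ref)
        hit = match_with_edits(read, ref, 3)
        if oracle <= 3:
            assert hit is not None and hit.mismatches + hit.gaps == oracle
        else:
            assert hit is None

    def test_ungapped_mode_disallows_indels(self):
        ref = "TTTTACGTACGTACGTACGTTTTT"
        read = "ACGTACGACGTACGT"  # needs a gap to align well
        gapped = match_with_edits(read, ref, 2, gapped=True)
        ungapped = match_with_edits(read, ref, 2, gapped=False)
        assert gapped is not None
        assert ungapped is None or ungapped.gaps == 0


class TestSensePerfect:
    EST = [ESTRecord("e1", "AAAAGATTACAGATTACATTTTTTT", "protein_coding")]

    def test_sense_hit(self):
        r = UniqueRead("u", "GATTACAGATTACA", {"L": 1})
        h = match_sense_perfect(r, self.EST)
        assert h is not None and h.ref_id == "e1" and h.strand == "+"

    def test_antisense_only_is_none(self):
        r = UniqueRead("u", revcomp("GATTACAGATTACA"), {"L": 1})
        assert match_sense_perfect(r, self.EST) is None

    def test_absent_is_none(self):
        r = UniqueRead("u", "GGGGGGGGGGGGGGGG", {"L": 1})
        assert match_sense_perfect(r, self.EST) is None


def test_mirna_family_naming():
    assert mirna_family("ath-miR156a") == "miR156"
    assert mirna_family("osa-miR156b-5p") == "miR156"
    assert mirna_family("pap-miR2911") == "miR2911"
    assert mirna_family("miR-466") == "miR-466"
    assert mirna_family("weird_name") == "weird_name"


class TestCascade:
    """Hand-executed cascade oracle on a small toy set."""

    CODING = [ESTRecord("c1", "AAAATTTTGGGGCCCCAAAATTTTGGGGCCCC", "protein_coding")]
    NONCOD = [ESTRecord("n1", "TGCATGCATGCATGCATGCATGCA" + "A" * 20, "noncoding")]
    STRUCT = ReferenceSet("structural_rna", [
        ReferenceRecord("trna1", "tRNA", "GGCCGGTTAGCTCAGTTGGTAGAGCA")])
    MIRNA = ReferenceSet("known_mirna", [
        ReferenceRecord("ath-miR999a", "miR999", "TGCATGCATGCATGCATGCAT")])

    def classify(self, seqs):
        reads = [UniqueRead(f"u{i}", s, {"L": 4}) for i, s in enumerate(seqs)]
        recs = classify_reads(reads, self.CODING, self.NONCOD, self.STRUCT,
                              self.MIRNA, AlignParams())
        return reads, recs

    def test_coding_beats_mirna(self):
        # a read matching both a coding EST (sense) and a miRNA reference
        coding = [ESTRecord("c2", "TTTT" + "TGCATGCATGCATGCATGCAT" + "TTTT",
                            "protein_coding")]
        reads = [UniqueRead("u0", "TGCATGCATGCATGCATGCAT", {"L": 4})]
        recs = classify_reads(reads, coding, self.NONCOD, self.STRUCT, self.MIRNA)
        assert recs[0].category == "protein_coding"

    def test_structural_beats_mirna(self):
        # 2 edits from the tRNA, 0 from the miRNA: structural step wins
        trna_2mm = "GGCCGGTTAGCTCAGTTGGTAGAGCA"
        read = trna_2mm[:5] + "AA" + trna_2mm[7:]
        struct = ReferenceSet("structural_rna",
                              [ReferenceRecord("t", "tRNA", trna_2mm)])
        mir = ReferenceSet("known_mirna", [ReferenceRecord("m", "miR1", read[:21])])
        reads = [UniqueRead("u0", read, {"L": 4})]
        recs = classify_reads(reads, self.CODING, self.NONCOD, struct, mir)
        assert recs[0].category == "tRNA"

    def test_full_toy_cascade(self):
        seqs = [
            "AAAATTTTGGGGCCCCAAAA",          # sense hit on coding EST
            "TGCATGCATGCATGCATGCAT",         # perfect nc-EST + miRNA -> miRNA
            "GGCCGGTTAGCTCAGTTGGTAGAGCA",    # tRNA
            revcomp("TGCATGCATGCATGCATGCATGCA"),  # antisense nc-EST only
            "CTCTCTCTCTCTCTCTCTCTCT",        # nothing
        ]
        _, recs = self.classify(seqs)
        assert [r.category for r in recs] == [
            "protein_coding", "miRNA", "tRNA", "noncoding_est", "unmatched"]
        assert recs[1].family == "miR999"

    def test_missing_reference_set_is_config_error(self):
        with pytest.raises(ValueError, match="missing reference set"):
            classify_reads([], self.CODING, self.NONCOD, None, self.MIRNA)

    def test_categories_exhaustive_and_exclusive(self, dataset):
        from mirloom.preprocess import PreprocessConfig, preprocess_libraries

        res = preprocess_libraries(dataset.raw_reads,
                                   PreprocessConfig(contaminant_refs=dataset.contaminant_refs))
        recs = classify_reads(res.reads, dataset.coding_ests, dataset.noncoding_ests,
                              dataset.structural_refs, dataset.mirna_refs)
        assert len(recs) == len(res.reads)
        assert {r.read_id for r in recs} == {r.id for r in res.reads}
        # per-library category totals sum to the library post-filter total
        by_id = {r.id: r for r in res.reads}
        for lib, tot in res.library_totals.items():
            s = sum(by_id[r.read_id].counts.get(lib, 0) for r in recs)
            assert s == tot


def test_aggregate_families_sums_by_family(dataset):
    reads = [UniqueRead("u0", "TGCATGCATGCATGCATGCAT", {"root": 5, "leaf": 2}),
             UniqueRead("u1", "TGCATGCATGCATGCATGCAA", {"root": 1})]
    from mirloom.annotate import AnnotationRecord

    recs = [AnnotationRecord("u0", "miRNA", family="miR156"),
            AnnotationRecord("u1", "miRNA", family="miR156")]
    fams = aggregate_families(recs, reads)
    assert len(fams) == 1
    assert fams[0].reads == {"root": 6, "leaf": 2}
    assert fams[0].unique_reads == {"root": 2, "leaf": 1}
    assert aggregate_families([], []) == []
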