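"""Complementarity target scan vs an exhaustive oracle; homology transfer;
dual-site (TAS-like) detection."""

import numpy as np
import pandas as pd
import pytest

from mirloom.model import ESTRecord, revcomp
from mirloom.targets import (HomologyTransferInput, complementarity_scan,
                             detect_dual_site_transcripts, homology_transfer,
                             merge_methods, alignment_strings)

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def oracle_scan(mirna, transcript, max_mm=3, min_len=17, seed=(2, 12)):
    """Brute force over every offset and every qualifying miRNA sub-window."""
    n = len(mirna)
    hits = []
    for off in range(len(transcript) - n + 1):
        best = None
        for a in range(1, seed[0] + 1):
            for b in range(seed[1], n + 1):
                if b - a + 1 < min_len:
                    continue
                # terminal positions must be Watson-Crick matches
                if (mirna[a - 1], transcript[off + n - a]) not in WC:
                    continue
                if (mirna[b - 1], transcript[off + n - b]) not in WC:
                    continue
                mm = sum((mirna[p - 1], transcript[off + n - p]) not in WC
                         for p in range(a, b + 1))
                if mm > max_mm:
                    continue
                key = (mm, -(b - a + 1), a)
                if best is None or key < best[0]:
                    best = (key, a, b, mm)
        if best is not None:
            _, a, b, mm = best
            hits.append((off + n - b, off + n - a + 1, mm, b - a + 1))
    # overlap merge
    hits.sort()
    merged, cluster = [], []
    for h in hits:
        if cluster and h[0] < cluster[-1][1]:
            cluster.append(h)
        else:
            if cluster:
                merged.append(min(cluster, key=lambda x: (x[2], -x[3], x[0])))
            cluster = [h]
    if cluster:
        merged.append(min(cluster, key=lambda x: (x[2], -x[3], x[0])))
    return merged


def _implant(rng, mirna, pos, length=500, mutate=0):
    t = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    site = list(revcomp(mirna))
    for k in range(mutate):
        i = int(rng.integers(0, len(site)))
        site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
    return t[:pos] + "".join(site) + t[pos + len(site):]


class TestScan:
    MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt

    def test_exact_site_found(self, rng):
        t = _implant(rng, self.MIRNA, 100)
        sites = complementarity_scan("m", self.MIRNA, [ESTRecord("t1", t, "protein_coding")])
        assert len(sites) == 1
        s = sites[0]
        assert s.mismatches == 0 and s.alignment_length == 21
        assert s.span_1based == (101, 121)

    def test_gu_wobble_counts_as_mismatch(self):
        # site with a G:U opposition at miRNA position 5 plus 3 real mismatches
        mirna = self.MIRNA
        site = list(revcomp(mirna))
        n = len(mirna)
        # miRNA position 5 faces site index n-5; make it T opposite G -> G:U
        assert mirna[4] == "G"
        site[n - 5] = "T"
        for p in (14, 15, 16):
            i = n - p
            site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
        t = "A" * 50 + "".join(site) + "A" * 50
        sites = complementarity_scan("m", mirna, [ESTRecord("t", t, "protein_coding")])
        assert sites == []  # 4 mismatches total: G:U is not a match

    def test_short_alignment_rejected(self, rng):
        # complementarity only over miRNA positions 1-16 (length 16 < 17);
        # C padding cannot pair the remaining miRNA bases (C,C,A,A,T)
        mirna = self.MIRNA
        site = revcomp(mirna[:16])
        t = "CCCCCCCCC" + site + "CCCCCCCCC"
        sites = complementarity_scan("m", mirna, [ESTRecord("t", t, "protein_coding")])
        assert sites == []

    def test_three_mismatches_accepted_four_rejected(self, rng):
        t3 = _implant(rng, self.MIRNA, 80, mutate=3)
        t4 = _implant(rng, self.MIRNA, 80, mutate=4)
        s3 = complementarity_scan("m", self.MIRNA, [ESTRecord("t", t3, "protein_coding")])
        s4 = complementarity_scan("m", self.MIRNA, [ESTRecord("t", t4, "protein_coding")])
        assert all(s.mismatches <= 3 for s in s3)
        # 4 point mutations may land on the same spot; oracle decides
        assert [(x.start, x.end, x.mismatches) for x in s4] == \
            [(a, b, mm) for a, b, mm, _ in oracle_scan(self.MIRNA, t4)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mirna = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 21)])
        t = _implant(rng, mirna, int(rng.integers(0, 470)), mutate=int(rng.integers(0, 4)))
        got = complementarity_scan("m", mirna, [ESTRecord("t", t, "protein_coding")])
        expect = oracle_scan(mirna, t)
        assert [(s.start, s.end, s.mismatches, s.alignment_length) for s in got] == expect

    def test_invariants_on_reported_sites(self, rng):
        mirna = self.MIRNA
        t = _implant(rng, mirna, 200, mutate=2)
        for s in complementarity_scan("m", mirna, [ESTRecord("t", t, "protein_coding")]):
            assert s.mismatches <= 3
            assert s.covers_2_12
            assert s.alignment_length > 16
            a, b = s.mirna_window
            assert a <= 2 and b >= 12

    def test_alignment_strings_marks(self, rng):
        t = _implant(rng, self.MIRNA, 60)
        s = complementarity_scan("m", self.MIRNA, [ESTRecord("t", t, "protein_coding")])[0]
        mir, marks, tgt = alignment_strings(self.MIRNA, t, s)
        assert len(mir) == len(marks) == len(tgt)
        assert marks == "|" * s.alignment_length


class TestHomologyTransfer:
    def _inp(self):
        best = pd.DataFrame([
            {"est_id": "e1", "model_gene_id": "AT3G11440.1", "evalue": 1e-45},
            {"est_id": "e2", "model_gene_id": "AT3G11440.1", "evalue": 1e-20},
            {"est_id": "e3", "model_gene_id": "AT5G00001.1", "evalue": 1e-60},
        ])
        known = pd.DataFrame([
            {"family": "miR159", "model_gene_id": "AT3G11440.1"},
            {"family": "miR999", "model_gene_id": "AT5G00001.1"},
        ])
        return HomologyTransferInput(est_besthit=best, known_targets=known)

    def test_join_with_cutoff_and_presence(self):
        out = homology_transfer(self._inp(), {"miR159"})
        assert out == [("e1", "miR159")]  # e2 above cutoff, miR999 absent

    def test_family_absent_excluded(self):
        assert homology_transfer(self._inp(), {"miR172"}) == []

    def test_schema_error(self):
        bad = HomologyTransferInput(est_besthit=pd.DataFrame({"x": []}),
                                    known_targets=pd.DataFrame({"family": [],
                                                                "model_gene_id": []}))
        with pytest.raises(ValueError, match="missing column"):
            homology_transfer(bad, set())


def test_merge_methods_flags():
    from mirloom.targets import TargetSite

    site = TargetSite("miR159", "e1", 10, 31, 21, 0, True, (1, 21))
    site2 = TargetSite("miR172", "e9", 5, 26, 21, 1, True, (1, 21))
    out = merge_methods([site, site2], [("e1", "miR159"), ("e2", "miR399")])
    got = {(r["family"], r["transcript_id"]): r["method"] for _, r in out.iterrows()}
    assert got == {("miR159", "e1"): "both", ("miR172", "e9"): "method1",
                   ("miR399", "e2"): "method2"}


class TestDualSite:
    def test_two_sites_detected_in_order(self, rng):
        mirna = "AAGCTCAGGAGGGATAGCGCC"  # miR390-like
        t = _implant(rng, mirna, 60, length=400)
        t = t[:300] + revcomp(mirna) + t[300 + 21:]
        recs = [ESTRecord("tas", t, "protein_coding")]
        out = detect_dual_site_transcripts("miR390", mirna, recs)
        assert len(out) == 1
        tid, sites = out[0]
        assert tid == "tas" and len(sites) == 2
        assert sites[0].start < sites[1].start

    def test_single_site_not_reported(self, rng):
        mirna = "AAGCTCAGGAGGGATAGCGCC"
        t = _implant(rng, mirna, 60, length=400)
        assert detect_dual_site_transcripts("miR390", mirna,
                                            [ESTRecord("t", t, "protein_coding")]) == []

    def test_overlapping_windows_merge_to_one_site(self):
        mirna = "AAGCTCAGGAGGGATAGCGCC"
        t = "C" * 100 + revcomp(mirna) + "C" * 100
        out = detect_dual_site_transcripts("miR390", mirna,
                                           [ESTRecord("t", t, "protein_coding")])
        assert out == []  # one physical site only
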