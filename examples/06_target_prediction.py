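"""Complementarity target scan, homology transfer and TAS-like dual sites.

Plant miRNAs bind near-perfectly: a site must cover miRNA positions 2-12,
align over > 16 nt and carry <= 3 mismatches, with G:U counted as a
mismatch. The homology route transfers known model-organism target calls to
transcripts via best protein hits. A transcript with two sites for one
miRNA is a trans-acting-siRNA-like candidate.
"""

import numpy as np
import pandas as pd

from mirloom.model import ESTRecord, revcomp
from mirloom.targets import (HomologyTransferInput, complementarity_scan,
                             detect_dual_site_transcripts, homology_transfer,
                             merge_methods)

rng = np.random.default_rng(9)
mirna = "TGGAGCTCCCTTCATTCCAAT"  # miR159-family-like sequence
bases = np.array(list("ACGT"))
transcript = "".join(bases[rng.integers(0, 4, 600)])
transcript = transcript[:180] + revcomp(mirna) + transcript[201:]
est = ESTRecord("PATCx01", transcript, "protein_coding")

sites = complementarity_scan("miR159", mirna, [est])
for s in sites:
    print(f"site on {s.transcript_id}: positions {s.span_1based[0]}-{s.span_1based[1]}, "
          f"{s.alignment_length} nt aligned, {s.mismatches} mismatches")

transfers = homology_transfer(HomologyTransferInput(
    est_besthit=pd.DataFrame([{"est_id": "PATCx02", "model_gene_id": "AT3G11440.1",
                               "evalue": 1e-45}]),
    known_targets=pd.DataFrame([{"family": "miR159", "model_gene_id": "AT3G11440.1"}]),
), mirnas_present={"miR159"})
merged = merge_methods(sites, transfers)
print(merged.to_string(index=False))

# two implanted sites on a fresh transcript -> TAS-like locus
backbone = "".join(bases[rng.integers(0, 4, 600)])
tas = backbone[:100] + revcomp(mirna) + backbone[121:400] + revcomp(mirna) + backbone[421:]
dual = detect_dual_site_transcripts("miR159", mirna,
                                    [ESTRecord("TAS-like", tas, "protein_coding")])
print(f"dual-site transcripts: {[(t, [s.span_1based for s in ss]) for t, ss in dual]}")
# method1 finds organism-specific sites directly; method2 only inherits
# known targets -- the union is the point of running both.
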