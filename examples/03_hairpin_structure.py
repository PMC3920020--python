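"""Fold a designed precursor, locate the mature, derive the miRNA* and trim.

Shows the structural vocabulary the precursor filters speak: pair table,
terminal loop, core-region metrics, the 2-nt-overhang star span, and the
duplex +/- 10 nt trim that precedes the final fold.
"""

import numpy as np

from mirloom.structure import derive_star, fold, hairpin_metrics, locate_core, trim_precursor
from mirloom.synthetic import make_hairpin_est

rng = np.random.default_rng(7)
mature = "TTGACAGAAGATAGAGAGCAC"  # 21 nt, 5' U
est, mature_span, star_span = make_hairpin_est(mature, rng)

pt = fold(est)
print(pt.sequence)
print(pt.dotbracket)
print(f"MFE {pt.mfe:.1f} (builtin stacking model, arbitrary kcal/mol-like units)")

core = locate_core(pt, mature_span)
print(f"core: {core.length_bp} bp paired, {core.unpaired_count} unpaired, "
      f"{core.bulge_count} bulges")

duplex = derive_star(pt, mature_span)
print(f"mature span (1-based): {mature_span[0] + 1}-{mature_span[1]}   "
      f"star span: {duplex.star[0] + 1}-{duplex.star[1]}")

trimmed = trim_precursor(pt, duplex, flank=10)
metrics = hairpin_metrics(trimmed.pair_table)
print(f"trimmed precursor: {len(trimmed.sequence)} nt, MFE {trimmed.pair_table.mfe:.1f}, "
      f"terminal loop {metrics.terminal_loop_size} nt, branches {metrics.branch_count}")
# A clean candidate shows a fully paired core, loop <= 15 and no branches --
# exactly what the filter cascade requires.
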