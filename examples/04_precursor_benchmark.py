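"""Shuffle benchmark of the precursor filter cascade.

Trains the MFE-vs-length prediction interval on designed hairpins, then
scores 20 fresh hairpins (positives) against composition-preserving shuffles
of the same sequences (negatives). Sensitivity is the accepted fraction of
positives; specificity the rejected fraction of shuffles.
"""

from mirloom.precursor import FilterThresholds, benchmark, fit_mfe_regression
from mirloom.synthetic import mfe_training_table, training_hairpins

reg = fit_mfe_regression(mfe_training_table(20, seed=11))
print(f"MFE regression: mfe = {reg.intercept:.1f} + {reg.slope:.2f} * length "
      f"(n={reg.n}, residual sd {reg.residual_sd:.2g})")

positives = training_hairpins(20, seed=12)
sens, spec, audit = benchmark(positives, seed=13,
                              thresholds=FilterThresholds(), reg=reg)
print(f"sensitivity {sens:.2f}  specificity {spec:.2f}")
print(audit.groupby(["kind", "verdict"]).size().to_string())
# Shuffles keep base composition but destroy the stem, so they fail the
# structural rules or fall far outside the MFE interval.
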