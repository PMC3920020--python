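"""Desk arithmetic over the packaged published study tables.

Recomputes, from the packaged *P. aphrodite* survey tables: the miRNA share
of each library, miR159's share of all miRNA reads, the precursor length and
MFE ranges, the novel-precursor mean length, the 5'-U fraction, and the SPM
values behind the tissue-specificity flags.
"""

from mirloom import fixtures
from mirloom.discovery import five_prime_U_fraction
from mirloom.expression import family_share, rpm, spm, summarize

libs = list(fixtures.LIBRARIES)
cat = fixtures.category_counts()
totals = fixtures.library_totals()
mirna = cat[cat["category"] == "miRNA"].set_index("library")["total_reads"]

print("miRNA share of all small RNA reads (%):",
      {lib: round(100 * float(mirna[lib]) / totals[lib], 1) for lib in libs})

fam = fixtures.family_rpm().set_index("family")
shares = {lib: family_share(float(fam.loc["miR159", lib]),
                            rpm(int(mirna[lib]), totals[lib])) for lib in libs}
print("miR159 share of all miRNA reads (%):", shares)

prec = fixtures.conserved_precursors()
print(f"conserved precursors: n={len(prec)}, length {summarize(prec['length']).min}-"
      f"{summarize(prec['length']).max} nt, MFE {summarize(prec['mfe']).min} to "
      f"{summarize(prec['mfe']).max} kcal/mol")

nov = fixtures.novel_mirnas()
mean_len = nov.drop_duplicates("precursor_id")["precursor_length"].mean()
u, n = five_prime_U_fraction(list(zip(nov["read_id"], nov["mature_sequence"])))
print(f"novel precursors: mean length {mean_len:.0f} nt; {u}/{n} matures start with U")

for family, tissue in (("miR398", "leaf"), ("miR2911", "root")):
    vec = [float(fam.loc[family, lib]) for lib in libs]
    print(f"SPM({family}) in {tissue}: {dict(zip(libs, spm(vec)))[tissue]:.4f}")
# Values above 0.9 mark tissue-specific families -- the same computation
# scripts/acceptance.py reports.
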