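"""Browse the packaged random-coil reference tables.

Loads the side-chain pressure-coefficient database, looks up a few
records and recomputes a table footer.
"""

import hpcoil as hp

db = hp.load_reference()
print(f"{len(db)} coefficient records, {len(db.isotope_records)} isotope rows")

ala = db.lookup("Ala", "QB")
print(f"\nAla beta-methyl: delta0 = {ala.delta0} ppm, "
      f"B1 = {ala.b1} ppm/GPa, B2 = {ala.b2} ppm/GPa^2")

ratio = hp.curvature_ratio(ala)
print(f"curvature ratio B2/B1 = {ratio.ratio:.2f} +- {ratio.err:.2f} GPa^-1")
# a negative ratio means the pressure response saturates at high pressure

his = db.lookup("His", "HB2", "pH:4.0")  # His needs an explicit pH
print(f"\nHis HB2 at pH 4.0: B1 = {his.b1} ppm/GPa")

mean, sd = hp.table_footer_stats(db, "tab2")["b1"]
print(f"\nmean B1 over the 40 Hbeta records: {mean:.3f} ({sd:.3f}) ppm/GPa")
# shifts of beta protons move upfield with pressure on average
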