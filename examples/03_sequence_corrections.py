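"""Neighbor corrections of pressure coefficients along a sequence.

Sums the correction factors for an amide proton in a Leu-X-Asp-Trp
context and predicts a random-coil shift curve for an alanine methyl.
"""

import numpy as np

from hpcoil import SequenceContext, load_reference, neighbor_correction, predict_random_coil_curve

db = load_reference()
ct = db.correction_table

ctx = SequenceContext(sequence="LADW", index=1)  # target A, u=L, y=D, z=W
c1, c2 = neighbor_correction(ct, "HN", ctx)
print(f"HN correction for -Leu x Asp Trp-: C1 = {c1:+.2f} ppm/GPa, "
      f"C2 = {c2:+.2f} ppm/GPa^2")
# non-Gly neighbors, especially at i-1, make the amide response steeper

pressures = np.linspace(0.1, 200, 5)
shifts, corrected = predict_random_coil_curve(db, "GLAW", 2, "QB", pressures)
print("\nAla beta-methyl random-coil curve in GLAW "
      f"(corrections applied: {corrected}):")
for p, s in zip(pressures, shifts):
    print(f"  {p:6.1f} MPa   {s:.4f} ppm")
# deviations of a measured curve from this prediction signal structure
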