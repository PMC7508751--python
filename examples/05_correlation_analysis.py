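"""B1-B2 correlation analysis by side-chain position and chemical group.

The slope of B2 against B1 estimates the common curvature ratio of a
group of resonances far more robustly than averaging per-atom ratios.
"""

import warnings

from hpcoil import group_summary, load_reference

db = load_reference()

print("by side-chain position:")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for s in group_summary(db, "by_position"):
        if s.slope is None or s.slope_ci95 is None:
            continue
        print(f"  {s.label:4s} n={s.n:3d}  slope {s.slope:6.2f} "
              f"+- {s.slope_ci95:5.2f} GPa^-1   r = {s.pearson_r:5.2f}")

    print("\nby chemical group:")
    for s in group_summary(db, "by_chemical_group"):
        if s.slope is None or s.slope_ci95 is None:
            continue
        print(f"  {s.label:8s} n={s.n:3d}  slope {s.slope:6.2f} "
              f"+- {s.slope_ci95:5.2f} GPa^-1   r = {s.pearson_r:5.2f}")
# the beta protons correlate tightly (r ~ -0.8, slope ~ -1.4/GPa);
# the amide NH2 nitrogens stand out with a positive slope
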