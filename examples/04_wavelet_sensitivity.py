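"""Directional effect of wavelet filtering on cross-device agreement.

Simulates a 10-subject cohort of paired phantoms whose device-B volumes
differ by a small resolution mismatch, calibration scatter and noise, then
compares per-subband feature agreement: high-pass (HHH) features agree far
worse than unfiltered or low-pass (LLL) features.

Runtime: about 15 s.
"""

from crosspet import paired_tables_from_cohort, run_comparison

table = paired_tables_from_cohort(n_subjects=10, seed=0)
report = run_comparison(table)

print("image set   median r2   median ICC   % strong")
for name, g in report.summary["by_image_set"].items():
    print(
        f"  {name:<9} {g['median_r2']:9.3f} {g['median_icc']:12.3f} {g['pct_strong']:9.1f}"
    )

print("\npaired t-tests vs the unfiltered image (r2):")
for _, row in report.subband_tests_r2.iterrows():
    print(f"  {row['image_set']:<4} t = {row['t']:+6.2f}  p = {row['p']:.2e}")

# LLL tracks the unfiltered image closely (its difference is not significant)
# while every subband containing a high-pass letter, HHH most of all, shows a
# significantly lower median r2: high-pass coefficients isolate exactly the
# fine-scale content that device differences corrupt.
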