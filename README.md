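# crosspet

Cross-device comparability analysis of PET radiomic features.

## The problem

Quantitative PET image features — standardized uptake values (SUV), tumor
shape descriptors, and radiomic texture statistics — are increasingly used
as imaging biomarkers, for instance to judge eligibility for boron neutron
capture therapy from amino-acid-tracer PET (where a tumor-to-normal uptake
ratio above 2.5 is the usual criterion). But the same patient scanned on a
PET/CT and on a PET/MR does not yield identical feature values: the two
hybrid systems use different attenuation-correction maps and reconstruction
pipelines. Before features from the two devices can be pooled or
interchanged, each feature's cross-device agreement has to be quantified —
and, where agreement is linear but biased, a conversion equation fitted.

`crosspet` implements that workflow end to end for researchers in
quantitative imaging:

1. **SUV preprocessing** — decay-corrected SUV maps,
   `SUV(v) = C(v) · w / (D · 2^(−Δt/T½))` with tissue activity `C` (Bq/mL),
   body weight `w` (g), injected dose `D` (Bq) and the ¹⁸F half-life
   default `T½ = 6586.2 s`, followed by trilinear resampling to an
   isotropic 1.5 mm grid.
2. **Segmentation** — the hottest voxel seeds the tumor ROI; the ROI is the
   26-connected component of voxels with SUV ≥ 50 % of SUVmax.
3. **Feature panel** — a fixed 453-entry roster: 4 conventional features
   (T/N ratio, SUVmax/median/min), 8 shape features, and 16 histogram + 22
   GLCM + 11 GLRLM statistics computed on the original SUV image and on
   each of the eight single-level wavelet subbands LLL…HHH
   (4 + 8 + 9 × 49 = 453).
4. **Paired-device statistics** — per feature, an OLS fit
   `y = a·x + b` of device B on device A with `r²`, the intraclass
   correlation ICC(3,1) from the two-way subjects × devices ANOVA
   (consistency form), and a three-tier label: **strong** (r² > 0.85 and
   ICC > 0.75), **moderate** (r² > 0.5 and ICC > 0.5), **weak** otherwise.
   Strong and moderate features are exported with their interchange
   equation and its algebraic inverse. Paired t-tests compare each
   subband's 49 per-feature metrics against the unfiltered image.
5. **Synthetic paired phantoms** — ellipsoidal lesions with Gaussian-
   random-field texture on a low-uptake background, imaged through a shared
   scanner PSF; the second "device" is a smoothed, gain/offset-shifted,
   noise-perturbed rendition. Every stage of the pipeline is testable with
   known ground truth and no data download.

## Worked example

```python
from crosspet import paired_tables_from_cohort, run_comparison

table = paired_tables_from_cohort(n_subjects=10, seed=0)  # ~15 s
report = run_comparison(table)
for name in ("original", "LLL", "HHH"):
    g = report.summary["by_image_set"][name]
    print(name, round(g["median_r2"], 3), round(g["pct_strong"], 1))
```

prints

```
original 0.897 63.3
LLL 0.92 81.6
HHH 0.214 8.2
```

Unfiltered and low-pass-filtered features agree well between the two
simulated devices (median r² ≈ 0.9, majority in the strong tier), while
high-pass (HHH) features collapse to a median r² of about 0.2 with under
10 % strong — the high-pass subband isolates exactly the fine-scale image
content that device differences corrupt. The accompanying paired t-test
(`report.subband_tests_r2`) flags the HHH deficit at p ≈ 1e-18 while the
LLL-vs-original difference is not significant.

The `examples/` directory holds one short script per capability
(SUV + segmentation, panel extraction, comparability statistics, wavelet
sensitivity); each prints the numbers it computes and what they mean. A
thin CLI mirrors the library:

```bash
crosspet simulate phantoms --n-subjects 15 --seed 7 --out phantoms/
crosspet extract phantoms/s000_A.nii.gz --normal-mask phantoms/s000_normal.nii.gz \
    --subject-id s000 --modality A --no-resample --out tableA.csv
crosspet compare tableA.csv tableB.csv --out results/
crosspet report results/
```

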