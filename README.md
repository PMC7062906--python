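# marrowfat

Quantification of bone marrow fat in the midtibia from axial MRI, for
musculoskeletal researchers who need marrow adiposity estimates from
either chemical-shift fat/water images or plain T1-weighted scans.

Excess marrow adiposity is linked to low bone density and altered bone
development, and is elevated in children with movement disorders such as
cerebral palsy. Chemical-shift imaging (e.g. IDEAL fat/water
decomposition) measures it directly, but not every scanner offers it;
standard T1-weighted images are universal. This package implements both
quantification procedures, the agreement statistics used to compare them,
and a synthetic tibia phantom generator with known ground truth for
validating the whole pipeline.

## Methods in brief

Both procedures start from the T1-weighted stack: each slice is median
filtered, intensities are soft-clustered with fuzzy c-means, the
cortical-bone shell is identified as the dark ring and its hole-filled
interior becomes the **bone marrow mask**; the largest connected
component of the bright (fat) cluster is the **subcutaneous-fat
reference**. Analysis covers the middle third of the bone extent.

**Fat/water (IDEAL) procedure.** The marrow mask is transferred to the
co-registered fat and water images. Per slice, with mean signal
intensities SI over marrow voxels,

    BMFF (%) = 100 · SI_fat / (SI_fat + SI_water)

Fat area = BMFF × marrow area; bone marrow fat volume (BMFV) sums fat
areas over slices times the axial extent (slice thickness + gap); BMFF
is reported as the unweighted mean of per-slice fractions.

**T1 threshold procedure.** Per slice, the intensity threshold whose
above-threshold area inside an annulus bounding the subcutaneous ring
best matches the segmented subcutaneous-fat area is selected; marrow
voxels at or above that threshold count as fat. Areas and volumes
aggregate exactly as above.

**Agreement statistics.** Paired differences (T1 − IDEAL) with
Bland–Altman limits at mean ± 2 SD, Pearson correlation and paired
t-tests; Cohen's d = |m₁ − m₂| / √((s₁² + s₂²)/2) from group summaries;
two-group comparisons gated on Shapiro–Wilk normality (t-test, else
Mann–Whitney); and a normal-approximation sample-size formula.

## Worked example

```python
from marrowfat import PhantomConfig, PipelineConfig, run_pipeline

cfg = PhantomConfig(speckled=True, seed=11)   # 24 slices, true FF 0.80, Rician noise
out = run_pipeline(PipelineConfig(phantom=cfg, seed=11))
print(out.t1_result.summary())
print(out.ideal_result.summary())
```

prints

```
Bone marrow fat quantification (T1)
==============================================
slices analyzed          8  (range 8..15)
axial extent per slice   1.000 cm
BMFF (   slice-mean)     80.24 %
BMFV                        9.890 cm3
mean marrow area            1.541 cm2/slice

Bone marrow fat quantification (IDEAL)
==============================================
slices analyzed          8  (range 8..15)
axial extent per slice   1.000 cm
BMFF (   slice-mean)     79.57 %
BMFV                        9.808 cm3
mean marrow area            1.541 cm2/slice
```

The phantom's true fat fraction is 80%; over the analyzed middle-third
slices the true fat volume is 9.856 cm³. Both procedures land within a
fraction of a percentage point (fat fraction) and below one percent
(volume) of the truth. A cohort comparison wires the per-phantom
aggregates into the agreement layer:

```python
from marrowfat import run_cohort, sample_cohort_configs

df, bmfv_report, bmff_report = run_cohort(sample_cohort_configs(5, seed=3))
print(bmfv_report.summary())
```

```
Method agreement: BMFV_T1 vs BMFV_IDEAL  (differences are BMFV_T1 - BMFV_IDEAL)
====================================================
n pairs                  5
mean difference           0.0787
SD of difference          0.0684
limits of agreement      (-0.0582,  0.2155)   [mean +/- 2 SD]
Pearson r                 0.9992   (p = 2.628e-05)
paired t                  2.5706   (p = 0.06194)
```

i.e. the two procedures' fat volumes agree almost perfectly across
phantoms with a small positive bias of the T1 estimate — the same
qualitative behavior reported for the in-vivo comparison that motivated
the threshold procedure's validation.

A `marrowfat` command-line tool exposes the same stages
(`marrowfat phantom generate`, `segment`, `quantify ideal|t1`, `agree`,
`run`); see `marrowfat --help`.

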