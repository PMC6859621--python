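# oxytort

Retinal vessel oximetry and tortuosity analysis on dual-wavelength fundus
images, with cohort-level mixed-model statistics and a fully ground-truthed
synthetic fundus generator.

The package is aimed at ocular-imaging researchers who want to relate the
oxygen content of major retinal vessels to the shape of those vessels — for
example in sickle cell retinopathy (SCR), where chronic anemia and hypoxia
are suspected to drive vessels toward a more undulated course.

## What it computes

**Vascular oxygen content.** In a circumpapillary annulus spanning 1–2
optic-nerve-head (ONH) radii, vessels are detected with a Frangi vesselness
filter and their boundaries measured as the full width at half maximum
(FWHM) of intensity profiles taken perpendicular to the centerline every
5 px. Per wavelength the optical density is the average ratio of intensity
inside the vessel to intensity just outside it; the optical density ratio
ODR = OD₆₃₃/OD₅₃₂ (633 nm oxygen-sensitive, 532 nm near-isosbestic) maps to
hemoglobin saturation through a linear calibration SO₂ = a + b·ODR, and

    O₂ content = O₂max · HgB · SO₂ / 100      [mL O₂/dL]

with HgB derived from hematocrit (HCT/3) and O₂max = 1.34 mL O₂/g.

**Vessel tortuosity.** In the 1.5–5 ONH-radius annulus (on the 532 nm
image, vessels below 25 µm caliber excluded), centerlines are extracted by
skeletonization with photometric sub-pixel re-centering, smoothed with a
penalized cubic spline (regularization 3×10⁻⁵), and summarized by

    VTI = 0.1 · SDθ · N · M · (L_A / L_C)

where SDθ is the SD of chord-frame tangent angles (degrees), N the number
of critical points (sign changes of dy/ds in the chord frame), M the mean
arc/chord ratio of the sub-segments between inflection points, and L_A/L_C
the arc-to-chord ratio — and by the vessel inflection index VII, the count
of curvature sign changes. A straight segment has VTI = 0 and VII = 0; a
k-period sinusoid has exactly 2k−1 inflections.

**Cohort statistics.** Measurements are averaged per eye and vessel type,
outliers removed (±3 SD within diagnosis × vessel-type strata), and linear
mixed models fit with diagnosis, eye and vessel type as fixed effects, age
and mean arterial pressure (MAP = (SBP + 2·DBP)/3) as covariates, and a
per-subject random intercept (both eyes enter; the intercept absorbs their
correlation). Shannon entropy and mutual information (equal-width
histograms, log base 2) summarize the information shared by VTI and VII.

Because clinical fundus images of this kind are not publicly available, the
`synthetic` module provides an invertible forward model — vessels with
Gaussian cross-profiles whose FWHM equals the nominal caliber and whose
two-wavelength darkening encodes a known SO₂ — plus a two-group cohort
generator (healthy controls vs. SCR, whose low hematocrit reproduces the
anemia-driven O₂-content deficit) with exact geometric ground truth.

## Worked example

```bash
oxytort run-all --seed 1 --out demo        # 6+6 subjects by default config
```

or, in Python:

```python
from oxytort.config import PipelineConfig
from oxytort.pipeline import run_all

cfg = PipelineConfig(seed=1)
cfg.cohort.n_nc = cfg.cohort.n_scr = 6
run_all(cfg, "demo")
```

This renders 24 image pairs, measures them, and writes `demo/results/`.
The summary (`summary.txt`) for seed 1 reads:

```
Arteries
metric                 NC OD           NC OS          SCR OD          SCR OS
o2_content      17.00 ± 1.77    16.83 ± 1.62    10.01 ± 1.42    10.01 ± 1.66
vti              4.61 ± 0.75     4.90 ± 1.14     6.29 ± 1.12     6.64 ± 1.46
vii              7.88 ± 0.77     8.04 ± 0.87    10.25 ± 0.82    10.17 ± 0.61

Veins
metric                 NC OD           NC OS          SCR OD          SCR OS
o2_content      11.53 ± 1.14    11.63 ± 1.15     6.27 ± 1.34     6.41 ± 0.97
vti              3.59 ± 0.30     3.95 ± 0.47     5.35 ± 0.85     5.21 ± 0.35
vii              8.70 ± 0.75     8.47 ± 1.12    10.23 ± 1.50    10.17 ± 1.48
```

Arterial O₂ content is higher than venous, the SCR group sits well below
controls (the generator gives SCR subjects sickle-typical hematocrits near
27 %, so their blood simply carries less oxygen), and SCR vessels carry
about two extra inflection points. The mixed models
(`lmm_results.json`) recover a diagnosis effect on O₂ content of
β = −6.24 mL O₂/dL (p ≈ 2×10⁻⁸) and a negative O₂-vs-VII slope
(β = −0.35, p < 0.001); `entropy_mi.json` reports the entropies of VTI and
VII and their mutual information in bits. Re-running with the same seed
reproduces every table byte for byte.

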