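# femhu — 3D VOI Hounsfield-unit analysis of the proximal femur

`femhu` is an open, tested re-implementation of a 3D volume-of-interest (VOI)
workflow for opportunistic bone-quality assessment on routine CT: the proximal
femur is extracted from a HU-calibrated CT volume by seeded region growing,
cropped to the VOI running from the femoral head to the inferior margin of the
lesser trochanter, and summarized by a measurement quartet —

- **total volume** (cm³) of the VOI,
- **mean HU** over the VOI,
- **HUHA_fat**: percentage of VOI voxels with HU ≤ 0 (assumed fatty marrow),
- **HUHA_dense**: percentage of VOI voxels with HU ≥ 126 (dense cortical /
  trabecular bone),

with the full 1-HU histogram over [−1024, 3071] retained. The package also
implements the reliability statistics such a measurement tool needs:

- **ICC(A,1)** — single-measure, absolute-agreement intraclass correlation
  from the two-way ANOVA decomposition,
  `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`, with the F-based 95%
  CI and the conventional poor/moderate/good/excellent categories;
- **Bland–Altman** 95% limits of agreement, `mean ± 1.96·SD` of paired
  differences;
- **paired and Welch t-tests**;
- **exact noncentral-t power and sample size** for the paired t-test
  (noncentrality `d·√n`, df `n−1`).

Because no imaging data accompany the published workflow, the package ships a
first-class **digital phantom** module: stylized proximal-femur CT volumes
(cortical shell, trabecular/fatty-marrow interior, soft-tissue body, optional
adjacent bone, Gaussian noise, contrast-enhancement shifts) whose exact
composition is known, so every pipeline stage can be validated against ground
truth. Intended users: researchers evaluating opportunistic osteoporosis
screening on abdominopelvic CT, and anyone needing a reproducible, scriptable
alternative to commercial 3D VOI tools.

## Worked example

```python
from femhu import (PhantomSpec, generate_phantom, cortical_seed, run_case,
                   PowerSpec, power_paired_t, limits_of_agreement)

spec = PhantomSpec(noise_sd=0.0, random_seed=1)     # noise-free phantom
volume, gt = generate_phantom(spec)
report = run_case({"seed_voxel": list(cortical_seed(gt)),
                   "threshold_hu": 126, "cut_z_mm": 40}, volume=volume)
print(f"volume {report.total_volume:.2f} cm3  mean {report.mean_hu:.1f} HU  "
      f"fat {report.huha_fat:.2f}%  dense {report.huha_dense:.2f}%")
print("LoA:", limits_of_agreement(-2.24, 14.16))
print("power:", power_paired_t(PowerSpec(effect_size=0.5, alpha=0.05, tails=2), 50))
```

prints

```
volume 73.87 cm3  mean 478.1 HU  fat 22.62%  dense 77.38%
LoA: (-29.9936, 25.513599999999997)
power: 0.9338975812613688
```

The phantom report matches the phantom's ground-truth composition exactly
(22.62% of the VOI envelope was labelled fatty marrow at −80 HU); the
limits of agreement reproduce a published −30.0..25.5 HU interval from its
printed −2.24 ± 14.16 HU difference summary, and a paired design with 50
subjects has 93.4% two-tailed power at effect size 0.5.

The same pipeline is available from the shell:

```bash
femhu phantom --out ph --seed 1 --noise-sd 0
femhu run --volume ph/volume.nii.gz --seed 11,40,43 --cut-mm 40
femhu icc ratings.csv          # subject_id,rater_1,rater_2 CSV
femhu sample-size -d 0.5 --power 0.95 --tails 1
```

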