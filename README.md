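# fingermark

Colorimetric quantification of arginine in latent fingermark deposits, and
donor-level prediction of biological sex from it.

Latent fingermarks carry eccrine-sweat amino acids, and sweat arginine
averages roughly twice as high in females (94.8 ± 12.9 µM, SEM) as in males
(54.0 ± 12.6 µM).  The Sakaguchi reaction (arginine + α-naphthol + sodium
hypobromite under alkaline conditions) turns arginine into a red complex
whose color intensity is linear in concentration, so a flatbed scan of the
reaction's detection window is enough to quantify it — no spectrophotometer
required.  This package implements the image-analysis half of that workflow
for forensic researchers who have such scans (or want to simulate them):

1. **Segment** the detection window by hue/saturation color thresholding.
2. **Tint** the image red→magenta (replace the blue channel with a copy of
   the red channel), which sharpens the saturation response of the red
   complex.
3. **Measure** the mean HSB saturation S over the window
   (S = 100·(max−min)/max per pixel, in percent).
4. **Calibrate** a standard curve S = a + b·C by ordinary least squares on
   standards of known concentration C (µM), and estimate unknowns by
   inverse prediction Ĉ = (S − a)/b.
5. **Aggregate** each donor's prints (index, middle and ring fingers only —
   thumb and little-finger deposits are erratic and excluded), and call
   presumptive sex by the midpoint threshold between the two literature
   means, (94.8 + 54.0)/2 = 74.4 µM.
6. **Summarize** cohorts: mean ± SEM, Student-t 95 % CIs, pooled-SEM z-tests
   against literature values, Welch t-tests between groups, and blind-study
   accuracy scoring against ground truth.

Because no public image dataset exists for this assay, the package includes
a synthetic forward model (`fingermark.synthetic`) that renders
detection-window images whose saturation is linear in concentration, with
scanner-like pixel noise, and simulates donor cohorts with configurable
between-/within-donor variance, lifting-recovery loss and powder speckle.
Every downstream stage is tested against it.

## Worked example

Simulate a cohort the size of a small blind study (11 female and 4 male
donors, 3 prints each) and push it through the full pipeline:

```bash
fingermark simulate --seed 0 --n-female 11 --n-male 4 --out-dir cohort
fingermark report cohort/manifest.csv --seed 0 --out-dir results
```

`results/donors.csv` holds one row per donor:

```
donor_id,n_prints,donor_mean,presumptive,actual,match
F001,3,101.1,female,female,yes
F002,3,95.5,female,female,yes
F003,3,67.5,male,female,no
...
```

F003's three prints averaged 67.5 µM — below the 74.4 µM threshold — so the
donor is miscalled male.  `results/report.json` summarizes the cohort:

```json
"groups": {
  "female": {"n": 33, "mean": 84.7, "sem": 4.1, "ci95": [76.4, 92.9]},
  "male":   {"n": 12, "mean": 53.8, "sem": 4.6, "ci95": [43.5, 64.0]}
},
"comparisons": {
  "female_vs_literature": {"statistic": 0.75,  "p_value": 0.453, "significant": false},
  "male_vs_literature":   {"statistic": 0.019, "p_value": 0.985, "significant": false},
  "female_vs_male":       {"statistic": 5.009, "p_value": 2.57e-05, "significant": true}
},
"blind_study": {"matches": 13, "total": 15, "accuracy_percent": 87}
```

Both sex groups are statistically indistinguishable from the literature
sweat values but clearly different from each other, and 13 of the 15
donors are sexed correctly at this (deliberately noisy) default variance
setting.  The same steps are available as library calls — see
`fingermark.pipeline` — and `calibrate`, `quantify` and `classify` run the
stages individually.  All outputs embed the seed and a hash of the
effective configuration.

Real scans work the same way: point `quantify` at a manifest CSV
(`donor_id,sex,finger,image_path`) of 8-bit RGB TIFF/PNG images and a
calibration fitted from your own standard-series scans with `calibrate
--standards standards.csv`.

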