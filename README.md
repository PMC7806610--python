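# imsiq — quantitative immuno-mass-spectrometry imaging

`imsiq` is a processing pipeline for **immuno-mass-spectrometry imaging
(iMSI)**: mapping a protein in tissue sections by tagging its antibody with a
lanthanide (here Gd-158) and imaging the metal by laser-ablation ICP-MS.
The motivating application is quantifying **dystrophin**, the sarcolemmal
protein absent or reduced in Duchenne muscular dystrophy, where the metal
signal concentrates in thin rings along the muscle-fiber membranes and the
whole-image mean badly understates the biologically relevant concentration.

The package covers the full chain from raw line scans to replicate
statistics:

1. **Phantom simulation** — synthetic muscle sections (Voronoi fiber mosaic,
   membrane bands, optional revertant fibers) and simulated laser-ablation
   line scans with spot averaging and Poisson-plus-flicker detector noise,
   so every stage is testable without instrument data.
2. **Reconstruction** — raster assembly from line scans (pixel pitch =
   scan speed / acquisition rate by line pitch) and **super-resolution
   reconstruction (SRR)**: fusion of two orthogonal passes offset by half a
   line pitch onto a fine isotropic grid (≈1.76 µm pixels, ≈3.1 µm² per
   pixel for the 15 µm spot / 30 µm s⁻¹ / 20 Hz geometry).
3. **Filtering** — Gaussian smoothing and Richardson–Lucy total-variation
   (RLTV) deconvolution, with the pipeline deconvolving against the
   forward-model PSF of the fused reconstruction.
4. **Calibration** — unweighted OLS of mean intensity against
   matrix-matched gelatine standards (blank, 1.33 … 3523.06 ng g⁻¹), with
   LLOQ = 5 × SD of the calibrated blank and optional pre/post bracketing.
5. **Segmentation** — six reproducible methods: median, Otsu, Sauvola,
   Phansalkar, and globally optimal 1-D k-means / k-medians clustering
   (dynamic programming over contiguous partitions; no random
   initialisation). The default reports the pooled mean of clusters 2 and 3
   of a k = 3 clustering.
6. **Quantification** — masked mean per section, replicate mean/SD/CV%,
   single-pass one-sided Grubbs outlier test (G_crit = 1.938 for n = 7 at
   α = 0.05), and "< LLOQ" censoring.

## Worked example

Run the full pipeline on the default synthetic conditions — a 300 × 300 µm
section with 25 fibers, membrane concentration 500 µg kg⁻¹, interior
20 µg kg⁻¹, background 5 µg kg⁻¹, imaged as seven replicate serial
sections:

```sh
imsiq pipeline --seed 7 --output-dir out/
```

which prints the replicate summary:

```json
{
 "mean_ugkg": 460.866,
 "sd_ugkg": 6.45148,
 "cv_percent": 1.39986,
 "n_used": 7,
 "n_below_lloq": 0,
 "grubbs_removed": false,
 "cv_within_fda_limit": true
}
```

The k-means masked mean (460.9 µg kg⁻¹) recovers the true membrane
concentration of 500 µg kg⁻¹ within 8%, while the unsegmented whole-image
mean sits near 100 µg kg⁻¹ — the background/interior bias that makes
segmentation necessary. The replicate CV of 1.4% is far inside the 20%
bound used for ligand-binding assays, the calibration R² is 0.999996, and
the LLOQ evaluates to 70.9 µg kg⁻¹. Adding `--compare-segmentation`
tabulates all six methods on the same images:

```
    method  mean_ugkg  cv_percent  n_used  positive_fraction
    median 210.924215    0.099768       6           0.500000
      otsu 567.711527    2.279166       7           0.123509
   sauvola 218.632403    0.559990       7           0.462388
phansalkar 468.190494    1.387759       7           0.154382
    kmeans 460.865916    1.399861       7           0.184587
  kmedians 418.402399    1.150842       7           0.215424
```

showing the documented behaviours: the median threshold keeps half the
image and dilutes the mean, Otsu biases high with a thin mask, Sauvola
admits large swaths of locally-variable background, and the clustering
methods land nearest the truth.

Every stage is also available as its own subcommand (`phantom`,
`reconstruct`, `filter`, `calibrate`, `segment`, `segment-compare`,
`quantify`) and as library functions (`imsiq.srr_fuse`,
`imsiq.cluster_kmeans_1d`, `imsiq.grubbs_test`, …).

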