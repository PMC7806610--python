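# Methods

This note documents the models behind `imsiq`, the parameters that matter,
the numerical choices, and what the synthetic validation does and does not
demonstrate.

## The measurement model

A laser of spot diameter `spot_um` (default 15 µm) rasters a tissue
section at `scan_speed_um_s` (30 µm s⁻¹) while the ICP-MS integrates at
`acq_hz` (20 Hz), so consecutive samples are `speed/rate` = 1.5 µm apart
along the fast axis and ablation lines are `line_pitch_um` (15 µm) apart
along the slow axis. The expected signal at each position is the mean
analyte concentration under the spot; we model the spot as a uniform
(top-hat) disk by default, with a Gaussian profile (FWHM = spot diameter)
available — no beam profile measurement exists for this geometry, and the
top-hat matches how ablation removes material.

Detector counts per acquisition window are Poisson with mean
`(sensitivity × c + dark) / acq_hz`, rescaled to counts s⁻¹ and then
multiplied by `(1 + ε)`, `ε ~ N(0, flicker²)`, floored at zero — the
Poisson-plus-flicker noise characteristic of ICP-MS detection. Defaults
(`sensitivity` 5 cps per µg kg⁻¹, `dark` 240 cps, `flicker` 5%) were fixed
so that the blank gelatine standard maps to a blank SD near 13.8 µg kg⁻¹,
i.e. an LLOQ (5 × SD) at the ~69 µg kg⁻¹ scale typical of this assay.

## The phantom

Muscle cross-sections are emulated as a Voronoi tessellation of `n_fibers`
seed points (default 25 on 300 × 300 µm, mean fiber diameter ≈ 60 µm). A
band of `membrane_width_um` total thickness — every pixel within half a
width of an inter-label boundary — carries the membrane concentration
(default 500 µg kg⁻¹); interiors and background carry 20 and 5 µg kg⁻¹.
The 5 µm default band width is the apparent width of sarcolemmal
immunostaining at this pixel scale; the true lipid bilayer is far thinner,
but what the assay sees is the membrane-associated protein band. A seeded
Bernoulli draw marks a `revertant_fraction` of fibers whose membrane
concentration is multiplied by `revertant_boost` (default 10), emulating
sporadic fibers with restored expression in otherwise-null sections.

Replicate "serial sections" are simulated as independent noise
realisations over the same truth — an idealisation of consecutive 10 µm
sections, which in reality differ slightly in morphology. Consequences:
the simulated replicate CV (1–3%) reflects measurement noise only, and
real inter-section CVs (10–20%) driven by biology will be larger. Washout
and aerosol-transport tailing between pixels are not modelled.

## Super-resolution reconstruction

Each pass is strongly anisotropic (1.5 µm × 15 µm pixels). Two orthogonal
passes, the second offset by half a line pitch (7.5 µm), are resampled
onto a common isotropic grid — nearest-line assignment along each pass's
slow axis (a sub-pixel lies inside exactly one physical swath), linear
interpolation along the fast axis — and fused per pixel by the arithmetic
mean (geometric mean optional). The mean is unbiased for equal-noise
estimates, preserves uniform fields exactly, and makes the fused mean
equal the mean of the two resampled passes by construction. The pipeline's
target pitch default is 1.76 µm (≈3.1 µm² pixels); the library default is
`line_pitch/8` floored at 1.5 µm.

## Filtering and deconvolution

Two conditioning operations exist, applied identically to samples and
standards where they are applied at all:

* Gaussian smoothing (`gaussian_filter`), reflective boundaries, σ default
  2 px for standalone use.
* Richardson–Lucy deconvolution with total-variation regularisation
  (`rltv_deconvolve`): the multiplicative RL update divided by
  `1 − λ·div(∇e/|∇e|)`, λ default 0.01, which suppresses noise
  amplification while preserving edges. With λ = 0 it is classic RL:
  non-negative, flux-conserving under reflective boundaries, fixed on
  uniform images and delta PSFs.

Three pipeline-level choices matter and were set by convergence analysis
on the phantom:

1. **PSF = reconstruction forward model.** The fused image is
   (approximately) the truth blurred by the spot disk convolved with the
   average of one-line-pitch boxes along x and y (the swath replication of
   the two passes). Deconvolving with this PSF, rather than the bare spot
   disk, is what allows thin membrane bands to recover their true
   amplitude; with the bare disk, restoration stalls at ~65% of truth.
   Standalone `FilterParams` keeps the spot-disk default for images that
   are not SRR products.
2. **No unmodelled pre-blur.** A Gaussian applied before deconvolution but
   absent from the PSF caps membrane restoration at roughly half the true
   amplitude, so the pipeline's Gaussian default is σ = 0 and TV carries
   the noise control. The Gaussian stage remains available by config.
3. **Iterations = 400.** The effective PSF spans ~3× the membrane band
   width, and RL approaches the true band amplitude slowly from below in
   this regime. The recovered replicate mean, tracked at checkpoints from
   25 to 400 iterations, rises monotonically (≈330 → 375 → 426 → 477 →
   496 µg kg⁻¹ at 25/50/100/200/300 on a reference run) and flattens near
   truth around 300–400 iterations without overshooting; 400 is the
   default. Runtime is ~2 s per 170×170 image.

Standards are conditioned with the Gaussian stage only: a uniform block
never passes through the SRR operator, deconvolution of a flat field
carries no information while amplifying the blank noise that defines the
LLOQ, and both filters preserve the mean, so the calibration transfer is
identical either way.

## Calibration and LLOQ

Unweighted OLS of mean intensity against assigned concentration
(1/x-weighting is deliberately not the default; the simulated and typical
measured standard noise is close to proportional only at the extremes and
the assay reports simple linearity). A model with slope ≤ 0 is flagged
unusable. Concentration conversion `c = (I − b)/a` clamps negatives to
zero for reporting, but the LLOQ uses the **unclamped** blank residuals —
truncating the blank distribution at zero would understate its SD. LLOQ =
5 × SD(blank), with the blank being the lowest gelatine level. Pre/post
bracketed calibrations are averaged (slope, intercept), reporting the
minimum R² and the relative slope drift; whether the original workflow
averaged or used the curves separately is not documented, so averaging is
the stated default.

## Segmentation

Six methods, all deterministic:

* **median** — keep pixels ≥ the image median (ties kept).
* **Otsu** — maximise between-class variance on a 256-bin histogram; an
  exact-value variant over unbinned cuts backs the k-means equivalence
  test (optimal 2-means and exact Otsu coincide).
* **Sauvola** — `T = m(1 + k(s/R − 1))` on 15-px local windows, k = 0.5,
  R = half the dynamic range.
* **Phansalkar** — `T = m(1 + p·e^{−qm} + k(s/R − 1))` on [0,1]-normalised
  data, k = 0.25, p = 2, q = 10, R = 0.5 — both per the methods' original
  publications.
* **k-means / k-medians** — globally optimal 1-D clustering by dynamic
  programming over contiguous partitions of the sorted values (divide-and-
  conquer, O(k·n·log n) on weight-collapsed unique values). No random
  initialisation; ties break toward the leftmost optimal split, so results
  are bit-reproducible. Default k = 3 with the pooled pixel mean over
  clusters 2 ∪ 3 reported ("averaging the second and third clusters" is
  read as the pooled mean; the mean-of-cluster-means alternative is a
  flag). `select_k` emits WCSS, elbow drops and BIC for k = 2..9 but makes
  no automatic choice — elbow/BIC selection is unreliable on these
  histograms, and k = 3 is the operator default.

Clustering runs on all pixels, including off-tissue background, keeping
the segmentation free of manual ROI choices.

## Quantification

Masked mean per section; sections below the LLOQ are reported as "< LLOQ"
and excluded from replicate statistics. The Grubbs test is one-sided at
α = 0.05 — this convention reproduces the tabulated critical value 1.938
for n = 7 (two-sided would give ≈2.02) — and removes at most one value per
replicate set, since iterating the test inflates the type-I error. SD uses
the n−1 denominator throughout; CV% = 100·SD/mean.

## Numerical details

* RL intermediate divisions guard with 1e-12; the TV divisor is clipped at
  0.1; non-finite intermediates raise with the iteration index.
* The clustering DP's divide-and-conquer relies on the concave-Monge
  structure of the SSE/SAE costs; equivalence with exhaustive enumeration
  is property-tested for n ≤ 12, k ≤ 4.
* Report JSON rounds floats to 6 significant digits so byte-identical
  reruns are achievable; all randomness derives from one top-level seed
  fanned out via `SeedSequence`.
* Problem sizes: the validation pipeline uses a 300 × 300 µm phantom at
  1 µm truth resolution, seven replicates, two passes of 20 × 200 samples
  each, and a 1.76 µm fused grid (≈29 k pixels) — about 25 s end to end on
  one CPU.

## What passing the synthetic validation shows — and what it does not

The phantom validation demonstrates that the implementation chain is
self-consistent: geometry, calibration transfer, deconvolution and
cluster-based masking jointly recover a known membrane concentration
within 15% where the naive whole-image mean errs by >80%, with replicate
CVs well inside the 20% ligand-binding-assay bound. It does not
demonstrate accuracy on real tissue, where section-to-section morphology,
antibody binding stoichiometry, matrix effects and ablation-cell washout
all contribute variance and bias that the generator deliberately omits.
Tissue-derived reference values (e.g. wild-type vs dystrophin-null
concentrations) require instrument data and are outside what this package
can reproduce.
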