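# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the tests demonstrate.

## Coordinate frame and volume model

All rasters are RAS+ MNI millimetres with 0-based voxel indices; a voxel's
coordinate is its centre and the affine is stored in the NIfTI sform. The
default grid is a 53×63×52 box at 3 mm spanning MNI
[−78, 78] × [−112, 76] × [−50, 103]. The exact normalised bounding box of
the clinical protocol is not published, so this box is a stand-in chosen to
cover the whole brain including the cerebellum; the brain mask is the
box-inscribed ellipsoid inflated by 5% so peripheral network nodes
(cerebellar crus, orbitofrontal cortex) fall inside it. Both the voxel size
and the mask are configurable.

Smoothing is mask-aware renormalised Gaussian convolution (the smoothed map
is divided by the smoothed mask), so constants are preserved up to the mask
edge; the kernel σ per axis is FWHM / (√(8 ln 2) · voxel size), default
FWHM 6 mm. Local maxima are suprathreshold voxels that are ≥ all 26
neighbours, greedily suppressed in descending-value order at a minimum
separation of 8 mm (the peak-table convention of common SPM workflows; the
protocol itself states none).

## Synthetic BOLD generator

The raw clinical imaging data are not shared, so validation rests on
synthetic runs that carry exactly the structure the analysis assumes:

- **Networks** are sums of isotropic Gaussians (σ = 6 mm, amplitude 1) at
  anatomical node coordinates. LANG and SN nodes are the published group
  peaks of the cohort's language and cingulo-opercular systems; VAN, DAN,
  lFPC, DMN and VIS nodes are literature-conventional coordinates chosen
  for this package and recorded in `langmap/data/templates.yaml` — they are
  implementation conventions, not claims about any cohort.
- **Resting runs**: data = Σₖ mapₖ ⊗ sₖ(t) + ε, where each sₖ is a
  unit-variance series with Laplacian innovations band-limited to
  0.01–0.1 Hz by Fourier masking (so ≥ 95% of its power is in-band while
  retaining positive excess kurtosis), and ε is white Gaussian noise of
  sd 1 inside the mask. Spatial ICA identifiability comes primarily from
  the super-Gaussian (sparse-blob) *spatial* marginals; the non-Gaussian
  time courses additionally avoid degenerate mixing.
- **Task runs**: data = effect · map ⊗ (SG boxcar ∗ HRF) + drift + ε with
  16-s alternating SG/TL epochs tiling the run (38 full epochs for 270
  volumes at TR 2.28 s; the tail is baseline). The first epoch starts after
  the three to-be-discarded volumes so that volume discard plus onset shift
  leaves a design starting at t = 0. Drift is a global random Legendre
  polynomial (order 3, unit amplitude, 1/k-weighted coefficients).
- Every generator is a pure function of its arguments including the seed;
  identical seeds give bitwise-identical runs.

Defaults mirror the clinical acquisition: 270 volumes, TR 2.28 s, 3
discarded volumes, 3 mm grid. What the generator deliberately omits:
physiological (cardiac/respiratory) noise, head motion, susceptibility
distortion, temporally autocorrelated noise, and lesion-induced signal
dropout. Passing recovery tests therefore demonstrates the correctness of
the analysis chain, not its robustness to those real-data effects.

## Task GLM

Voxel-wise ordinary least squares. The design holds the SG and TL boxcars
sampled at volume times and convolved with the canonical double-gamma HRF
(gamma-density difference, response peak 6 s, undershoot 16 s, unit
dispersions, undershoot ratio 1/6, 32-s support, peak-normalised), a
DCT-II drift basis with ⌊2·duration/128 s⌋ columns (9 for a 267-volume
run), and an intercept; no global-signal regressor. dof = rows − rank.

Numerical notes: β recovery on noise-free, drift-free runs is exact to
machine precision. The polynomial drift is *not* exactly inside the DCT
span; its residual reaches ~10% of its amplitude at the run edges, but its
leakage into the SG−TL contrast stays below 1% of the effect size (tested),
which is the operative claim. Voxels with zero residual variance have an
undefined t and are removed from the map's mask rather than set to 0.

Multiple comparisons: voxel-level FWE is Bonferroni over in-mask voxels —
deliberately not random-field theory, which would need smoothness
estimation; Bonferroni is conservative and exactly testable (Monte-Carlo
family-wise error 0.048 under the white null vs. the nominal 0.05, with
theory 1−(1−α/n)ⁿ = 0.0488). Cluster-level FDR forms clusters at voxel
p < 0.001 (26-connectivity), computes each cluster's p against a
permutation null of the *maximum* cluster size (Freedman–Lane residual
permutation for the GLM; sign-flipping for paired maps; 500 permutations by
default, seeded), and applies Benjamini–Hochberg across clusters. No
prewhitening is applied; the generator's noise is white, and this is a
documented limitation for autocorrelated real data. The two-session
protocol is handled by fitting sessions separately and pooling contrasts.

## Spatial ICA

Orientation is fixed as spatial ICA: voxels are the realisations, sources
are spatial maps, time courses are mixing columns (the transposed
orientation is a classic implementation bug; the orientation is asserted by
the recovery tests). The chain is: per-voxel temporal mean removal, SVD
reduction to k components with whitening, then extended Infomax —
natural-gradient ascent with the kurtosis-switching tanh rule, trained in
seeded random blocks (block ≈ √(N/3), capped at 32 blocks/pass), learning
rate 0.15 on the block-averaged gradient with 0.98 per-pass decay plus
angle-triggered annealing, stopping when the per-pass weight change falls
below 1e−6. Natural-gradient ascent can stall in a local optimum where two
sources remain mixed, so 3 seeded restarts from random orthogonal
initialisations are run and the solution whose unit-variance sources have
the largest mean |excess kurtosis| is kept — a standard model-selection
criterion that never consults ground truth. Everything is deterministic
given the config seed.

Component maps are z-scored over the mask and sign-fixed to positive
skewness, making "activation" positive and the z = 2 display/selection
threshold meaningful; components are ordered by explained temporal
variance. The component count defaults to 55 (the clinical choice for
267-volume runs) but is validated against the achievable data rank;
desk-scale synthetic analyses use 8–20 components, because the component
count is a tunable of the method, and 55 exceeds what short synthetic runs
support. MNE's Infomax implementation serves as an independent oracle in
the tests, never as the implementation.

A note on resolution: ICA recovery needs the network variance to clear the
PCA noise floor (the Marchenko–Pastur edge). At 3 mm each σ = 6 mm node
spans ~45 voxels and 6-mm smoothing suppresses white noise ~10-fold, so
planted networks are recovered with spatial correlation ≥ 0.95; at 6 mm
voxels the same nodes span ~6 voxels and recovery collapses. Desk-scale
configurations therefore keep the native 3 mm resolution and shorten the
run (150 volumes) instead.

## Network identification

Two human raters' consensus is replaced by a deterministic rule engine over
component peaks (z > 2, 8-mm separation) matched to 12-mm spheres at named
anatomical regions (`langmap/data/atlas.yaml`). Rules: LANG = MTG + IFG +
ANG (unilateral or bilateral); VAN = supramarginal/TPJ + IFG with an
angular-gyrus veto (the ANG-vs-SMG opposition is the LANG/VAN
discriminator); SN = dACC + posterior pre-SMA + AIFO; DAN = IPS + FEF +
lateral occipital; lFPC = DLPFC + orbitofrontal with a posterior-MTG veto.
Fully satisfied rules compete by summed matched-peak z, then by fixed
priority (LANG, VAN, SN, DAN, lFPC); a component satisfying no rule is
"unclassified", and the selected language component is the LANG-labelled
one with the strongest evidence (ties → lower index). The
`classification_report` table (one row per component, Left/Right/Bi/No per
region) is the auditable analogue of the raters' worksheet.

## Laterality

Mass-based index: LI = 100·(R − L)/(R + L) over suprathreshold statistic
mass, with a ±5 mm midline exclusion. **Positive = right-hemisphere
dominance**, following the reference cohort's table convention — the
opposite of the common LI-toolbox sign. The threshold defaults to the
modality's own (z = 2 for components, 0 on already-thresholded t maps).
When no suprathreshold mass remains the index is undefined and reported as
such, never silently 0. Bootstrapped/threshold-free LI curves are out of
scope. Dominance classification is sign-only by default; an optional
|LI| < band "bilateral" mode exists because the published dominance cutoff
is ambiguous.

## Concordance

A stimulation site is detected when a peak lies within 10 mm (Euclidean,
peak-to-site) or, when only a region label is available, inside the
region's atlas spheres on the recorded side. A patient counts as detected
only if *every* positive site was. Sensitivity = detected / CM-positive,
to one decimal. The bundled fixture encodes the reference cohort's
stimulation outcomes at the region-label level (real coordinates were never
published); sites the resting-state analysis localised but the task
contrast missed are flagged `rest_only`. The published series states 32
CM-positive patients while printing 31 site rows; the fixture carries the
unlisted patient as an explicit reconstruction row (patient id 0, site
"unspecified", detected by both modalities), the only completion consistent
with both published sensitivities, and documents it in the loader.

## Cohort statistics

Means use listwise missing-value exclusion (one patient's scores are NA and
stay NA; n = 49 for the score means) and n−1 standard deviations.
Histology grouping: {GB, GS, AA, OD, OA III} high-grade glial; {XA, OA II,
PA, GG, AB} low-grade glial; lung-adenocarcinoma rows metastasis;
{cavernoma, AVM, DNET, radionecrosis} nontumoral (DNET grouped clinically
with the nontumoral lesions despite being a tumour histologically). This
code-level grouping reproduces the published totals of 42 glial, 2
metastases and 6 nontumoral lesions; the published 32/10 high/low split
comes out 33/9 from the printed histology codes — the discrepancy is
carried, not resolved. The comparison against the healthy-volunteer
summary statistics uses a Welch two-sample t-test from summaries (the
volunteer raw data are unavailable); whether the original analysis used
Welch, pooled-variance or a nonparametric test is unstated.

## Problem sizes

Simulation-backed tests and the acceptance script use: a 20³ voxel box
(3 mm) with six compact two-node templates, 150 volumes, and 10 components
for ICA recovery; the full 3-mm MNI box with all seven shipped templates,
150 volumes and 10 components for network identification and the
end-to-end demo; 12³/10³ boxes and 120–150 volumes for GLM recovery and
the 1000-map family-wise-error Monte Carlo. These sizes are the package's
desk-scale configuration; every protocol constant (TR, epoch length,
discard count, smoothing, thresholds, concordance radius) keeps its
clinical value throughout.

## Known limitations

- No slice-timing, motion, susceptibility or physiological-noise handling:
  synthetic data are generated directly in template space.
- White-noise GLM (no AR prewhitening); Bonferroni rather than
  random-field-theory FWE.
- The Infomax "customisation" used clinically is unpublished; the standard
  extended Infomax is implemented.
- Atlas geometry for VAN/DAN/lFPC and all rule thresholds are explicit
  package conventions where the published criteria were narrative.
- Sensitivity but not specificity: detecting false positives would require
  whole-surface stimulation mapping, which the reference data cannot
  support.
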