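# Methods

`fibroscar` reimplements, as a tested pipeline on synthetic data, a
two-arm computational analysis of fibrotic remodelling in infarcted
myocardium: (1) binary healthy-vs-pathologic classification of two-channel
multiphoton microscopy (MPM) planes from radiomic texture features, and
(2) four-class (muscle / necrotic / granulated / fibrotic) classification
of Raman microspectra with PLS-DA. No real tissue data ship with the
package: a first-class synthetic-data module emulates the class-dependent
structure of both modalities, and every downstream stage is exercised
against those phantoms.

## Synthetic MPM phantoms

Each plane holds an SHG channel (fibrillar collagen) and a TPEF channel
(cardiomyocyte autofluorescence). Collagen fibers are rendered as
anti-aliased polylines traced by bounded random walks: the initial heading
is von Mises distributed with per-class concentration κ (high κ → parallel
aligned fibers; κ → 0 → a random mesh), and each 4-px step perturbs the
heading by a Gaussian increment whose standard deviation is the class
"curliness". Fibers reflect at the frame borders. The rendered skeleton is
thickened by a Gaussian of σ = width/2, peak-normalized, and scaled by the
class SHG intensity. TPEF laminae are an oriented sinusoid (sharing the
plane's dominant orientation with the SHG fibers, as muscle laminae and
perimysial collagen co-align) modulated by a smooth random field and the
class TPEF intensity scale. Both channels then receive additive Gaussian
noise (sd 0.03), a Gaussian blur (σ = 1 px) standing in for finite optical
resolution, and are clipped at zero.

The per-class parameter table encodes the histologic progression: SHG
fiber count rises 6 → 18 → 34 → 50 and fiber width 1.2 → 2.8 px from
healthy to fibrotic while alignment falls (κ: 8 → 0.5) and curliness rises
(0.06 → 0.6); TPEF intensity falls 1.0 → 0.22. These orderings are
asserted as generator invariants. Default plane size is 256×256 px (a
desk-scale proxy; physical field of view is not modelled). The default
cohorts are 56 healthy + 128 pathologic training
planes over 3 ROIs (pathologic split 43/43/42 across necrotic, granulated,
fibrotic) and 378 test planes over 6 ROIs; planes are assigned
round-robin to ROIs (per-ROI counts beyond the totals are uniform by
construction).

What the phantoms do **not** emulate: optical physics (phase matching,
depth attenuation, PSF anisotropy), instrument noise statistics (Poisson
shot noise; the phantom noise is Gaussian), inter-animal variability, and
pathologist-level ambiguity at class boundaries. Passing the recovery
tests therefore shows the pipeline recovers planted class structure, not
that real ovine tissue would be classified at the same rates.

## Preprocessing and masking

Planes are block-average binned (default factor 1 at 256×256), per-plane
normalized (min-max by default; z-score available), and masked per channel
by Otsu's threshold followed by a binary opening with a 1-px disk to
suppress single-pixel speckle. The working ROI is the pixelwise OR of the
SHG and TPEF masks — the union captures the full tissue footprint at the
cost of admitting some background into the SHG channel, which the
classifier comparison tolerates. A fixed-threshold path models manual
thresholding; a config switch selects per-channel masks instead of the OR
mask.

## Radiomic features

152 features per channel, 304 per plane, with standard IBSI-style 2D
definitions: local intensity (2), intensity statistics (18), intensity
histogram (23), GLCM (25), GLRLM (16), GLSZM (16), GLDZM (16), NGTDM (5),
NGLDM (17) and 2D mask morphology (14). The registry is versioned and
configurable; its composition is a package choice that realises the
152-feature count from standard IBSI families. Numerical conventions:

- discretization: fixed bin number, N_g = 32, computed in-mask per channel
  (appropriate for arbitrary-unit microscopy intensities); constant
  regions map to level 1;
- directional matrices are computed for 0°/45°/90°/135° and summed before
  feature computation (merged aggregation); rotation by 90° leaves them
  invariant;
- neighborhoods are 8-connected and mask-respecting; NGLDM uses dependence
  count j = 1 + similar neighbors with α = 0 at Chebyshev radius 1;
- zones are 8-connected; zone distance is city-block distance to the ROI
  border (border = 1), computed on a zero-padded mask so image edges count
  as border;
- local/global intensity peak use a 5-px disc (the radiology 1-cm³
  convention has no microscopy analogue; the radius is configurable);
- logarithms are base 2; population moments throughout; the texture
  strength denominator carries a machine-epsilon guard so single-level
  images yield 0.

Every texture feature is validated against naive enumeration oracles on
random ≤10×10 fixtures to 1e-10.

## Binary classification protocol

Per Monte-Carlo fold: (1) greedy mRMR ranking on the fold's training rows
only — relevance and redundancy are plug-in mutual informations on
4-quantile-discretized features, ties broken by column order — keeping the
top d = 9 features (the d ≈ √n heuristic is surfaced as a warning, not
enforced); (2) SMOTE balancing of the
healthy minority (synthetic rows x + t(x_nn − x), t ~ U(0,1), k = 5
neighbors) to majority count; (3) fitting four classifier families —
ridge-regularized logistic regression, a 100-tree random forest, 5-NN, and
an RBF-kernel SVM with probability outputs — all standardized where
scale-sensitive. Validation sets hold round(0.2 × minority) planes per
binary class (11+11 for the default cohort, leaving 162 training rows
SMOTE-balanced to 117 per class); folds are pairwise distinct by rejection
sampling on the validation set. Selection and SMOTE never see validation
rows. Default 20 folds, seeds fanned out from a root seed via
`SeedSequence`.

At test time every classifier from every fold votes; a plane's ρ is the
arithmetic mean of all pathologic probabilities, its label the classifier
majority with even splits resolved by ρ ≥ 0.5 → pathologic. Pathologic is
the positive class for accuracy/sensitivity/specificity.

## Raman arm

Synthetic spectra are sums of Lorentzian bands at 728, 750, 869, 937,
1260, 1302, 1338, 1446, 1650, 2880 and 2920 cm⁻¹ on a 2 cm⁻¹ grid covering
600–1800 and 2700–3100 cm⁻¹ (the silent region omitted), plus a cubic
random baseline emulating autofluorescence and Gaussian channel noise
(sd 0.01). Collagen-associated band amplitudes rise monotonically along
muscle → fibrotic with band-dependent increments (early rises for
proline/amide III/CH₂ twist, late rises for the backbone C–C bands, so
class mean shapes are not collinear); the CH-stretch bands fall; amide I
(1650 cm⁻¹) carries the largest inter-class range, reflecting its
sensitivity to collagen fiber packing. These trends are enforced as model
invariants.

Preprocessing: despiking (median-filter residual z > 8 replaced by local
median), asymmetric-least-squares baseline removal (λ = 1e5, p = 0.01, 10
iterations), Savitzky-Golay smoothing (window 9, order 3), vector
normalization. This order with conservative defaults is the conventional
chemometrics choice; each step is switchable.

PLS-DA is NIPALS PLS2 of mean-centered spectra onto mean-centered one-hot
class indicators, k = 4 latent variables (one per class; LV1/LV2 serve
visualization). The inner power iteration runs to a 1e-13 change in the
unit-norm weight vector; each component is sign-fixed so its
largest-magnitude loading element is positive. Regression coefficients
B = W(PᵀW)⁻¹Qᵀ; prediction is argmax over indicator columns with ties
going to the first class in the canonical order muscle, necrotic,
granulated, fibrotic. Components are verified against an exact
SVD-per-deflation oracle (1e-8) and cross-checked against an independent
PLS2 implementation. Evaluation uses leave-one-out cross-validation as
the default harness; overall sensitivity/specificity are
unweighted macro means over the four one-vs-rest rates.

## Pipeline and reproducibility

A single root seed is spawned into per-stage seeds
(`SeedSequence.spawn`), so identical config + seed reproduces every
metric bit-for-bit; the run report records the config hash and all stage
seeds. Problem sizes used by the shipped tests and the acceptance script
are the default study-design cohorts (184 training / 378 test planes at
256×256; 40 spectra per class), except that the end-to-end determinism
check runs on a reduced cohort — determinism is size-independent — and
validation-side checks that only need fold structure use 3–5 folds.

## Known limitations

- The 152-feature roster is this package's registry; other engines
  realise the same count with different rosters.
- SMOTE, mRMR and the classifier roster parameterizations are design
  choices; all are config surface.
- GLDZM distance uses city-block metric; other IBSI-permitted metrics are
  not implemented.
- The NGLDM dependence-count percentage is identically 1 under
  mask-respecting counting; it is retained for registry completeness.
- Phantom realism limits noted above: headline rates on synthetic cohorts
  (near-perfect separation) exceed what heterogeneous real tissue yields.
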