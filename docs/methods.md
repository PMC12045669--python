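# Methods

## Signal model and inversion

The forward model is the steady-state spoiled-gradient amplitude
S = A·sinα·(1−E1)/(1−cosα·E1) with E1 = exp(−TR/T1). Assumptions: ideal
spoiling, uniform flip angle (no B1 correction), and negligible T2*/TE
decay — at TE ≈ 96 µs even the short lung T2* loses well under a percent of
signal, so TE is recorded in `AcquisitionParams` for provenance but never
enters the computation. Flip angles are degrees at every interface and
radians only internally.

The closed-form inversion E1 = (A·sinα − S)/(A·sinα − S·cosα),
T1 = −TR/ln E1 is exact on 0 < S < A·sinα. Policy outside that domain:
scalar calls raise ("signal exceeds model ceiling"); map-level calls flag
the voxel NaN and count it, because magnitude noise guarantees such voxels
exist in real data. As S → 0 the inversion diverges, so T1 is capped at
`t1_max_ms` (default 5000 ms — far above any tissue of interest, tight
enough to bound background air) with a separate capped count. The inversion
is ill-conditioned where E1 → 0 (TR ≫ T1); the property tests therefore
exercise T1 ≥ TR, the regime the protocol (TR = 3.7 ms, T1 ≥ tens of ms)
actually occupies.

## Calibration

R1_pre is deliberately a scalar, not a map: the protocol measures the
pre-contrast flip-angle series in one distal, solution-free ROI. A and
R1_pre are fitted jointly to the four mean ROI signals — the ROI used for A
(enhancement-free lung) and the ROI used for R1_pre coincide, which is the
minimal self-consistent reading of a protocol that calibrates both in
distal lung. Initialization uses the classical linearization S/sinα =
E1·(S/tanα) + A(1−E1); `scipy.optimize.least_squares` then refines (A, T1)
on the exact equation with tight (1e−14) tolerances. The fit rejects
degenerate series (fewer than two distinct angles, non-positive signals, E1
outside (0,1)) and reports a relative-RMS residual.

## Concentration and amounts

C = (R1_post − R1_pre)/r1 per voxel, r1 = 3 mM⁻¹s⁻¹ per Gd³⁺ ion
(configurable). Negative raw concentrations are inevitable under noise
wherever true C ≈ 0; the policy is: keep the raw signed map, clamp to zero
for amount integration and the distribution metrics, and always report the
clamped count. Amounts are Σ C·v over a region (mM·mL ≡ µmol); invalid
(NaN) voxels contribute zero and are counted. Units are fixed throughout:
T1 ms, R1 s⁻¹ (R1 = 1000/T1), spacing mm, volumes mL, amounts µmol.

## Regions

One integer label per voxel (0 background, 1 TLV-only, 2 PER, 3 CER)
enforces disjointness structurally; TLV is the union {1,2,3}, so
PER ∪ CER ⊆ TLV by construction and CER is the complement of PER within the
enhancement. External masks are first-class inputs (shape must match, and
spacing within 1e−3 mm); the deep-learning segmentation used upstream of
such masks is intentionally out of scope — any source will do.

The fallback segmenter is transparent plumbing for phantom-driven work:
voxel-wise enhancement (post−pre)/pre thresholded at 1.0 (a 100% signal
increase — a declared convention, far above the noise floor at the SNRs of
interest) inside a supplied lung mask, small components removed
(< 20 voxels). The CER rule is morphological: close the enhanced mask
(radius 2 mm) to fill the hollow airway lumen — the enhanced wall is a thin
shell that a plain opening would erase — then open with a ball of the
central tube radius (1.6 mm) and keep the component connected to the
trachea seed ("auto" = centroid of the most cranial enhanced slice).
Structuring elements are anisotropy-aware (physical radii, not voxel
counts). The segmenter contains no randomness.

## Phantom

The generator's defaults are the study conditions of the ex vivo cohort the
package models: 144×144×110 grid at 0.78×0.78×1.0 mm, four airway
generations, 100 µmol Gd³⁺ instilled, target PDF 84%, target PVF 32.5%,
right-lung share 0.55 (right-dominant distribution in a small majority of
specimens). Geometry is defined in millimetres anchored at the grid centre,
so `with_resolution()` re-renders the identical thorax on any grid;
geometry that cannot fit raises with sizing advice.

Choices worth stating:

* **T1_pre = 800 ms** for degassed ex vivo lung tissue — the source
  protocol never states its tissue T1, so this default is explicit and
  configurable; consequently the rendered signal-enhancement percentages
  are *not* tuned to match any reported SE values (they are jointly
  determined by T1_pre and noise, neither of which is pinned down).
* **CER is the thin enhanced wall shell** (1.5 mm, under the ≤ 2 mm wall
  coating seen on such images), not the whole airway; the air-filled lumen
  core is TLV-only. This makes the phantom's CER volume (~2 mL) smaller
  than the cohort mean (4.75 mL) — a geometric consequence, not a target.
* **Amount distribution**: the peripheral share of the total amount goes to
  PER with weights rising linearly ventral→dorsal (gravity-dependent
  pooling, supine); right/left asymmetry is placement-driven (blob centres
  drawn from the right lung with probability `right_fraction`), so the
  amount share tracks the volume share rather than being forced exactly.
  The field is rescaled so the grid integral equals the instilled amount
  exactly; the truth PDF equals its target exactly by construction.
* **Noise** is additive zero-mean Gaussian on magnitude, floored at zero —
  a simplification of Rician statistics, adequate at the SNRs exercised and
  declared as a limitation. Noise lives in its own seeded stream, separate
  from the geometry seed, so one anatomy can be re-imaged under independent
  noise. `noise_sd_for_peripheral_snr()` derives the sd that yields a
  stated ROI-convention SNR in the post-contrast PER.
* Enhanced voxels (blob tissue and wall shell) render with the tissue scale
  constant A, consistent with the analysis assumption of a single global A;
  the lumen core and background render at A = 0 (air).

What passing phantom tests shows — and does not: the pipeline's estimators
are unbiased and tight under the stated signal model with congruent
pre/post geometry. Real data add motion, B1 inhomogeneity, Rician bias,
partial-volume mixing at region boundaries and imperfect masks, none of
which the phantom emulates.

## Problem sizes

Noiseless end-to-end recovery and the SNR-50 segmentation check run on the
full 144×144×110 grid. The five-noise-seed stochastic recovery uses the
same thorax at 96×96×72 (≈1.17×1.17×1.53 mm), which leaves the estimators'
behaviour unchanged while keeping repeated runs cheap; both sizes are the
package's own validation choices.

## Numerical conventions

Cohort statistics: arithmetic mean, sample SD (n−1), CoV = SD/mean·100%;
cohort PVF/PDF are means of per-specimen ratios, not ratios of pooled sums.
Profiles in quantity mode sum exactly (to float round-off) to the region
amount; area mode reports in-plane mask area per slice. MIPs are
NaN-ignoring per-ray maxima; rays entirely outside the analysis mask stay
NaN. All file I/O is NIfTI via nibabel with spacing from header zooms;
orientation metadata is not reinterpreted — volumes written by the package
use the canonical (right→left, ventral→dorsal, cranial→caudal) axis order
and external data may declare a different axis tuple explicitly.

## Known limitations

No B1/flip-angle-inhomogeneity correction; no Rician noise model; scalar
R1_pre (no pre-contrast map); the fallback segmenter's thresholds are
conventions, not learned; the phantom's airway tree is geometric (capsule
segments), not airway-CFD realistic; reported per-specimen T1↔concentration
pairs from the reference cohort are not mutually consistent with a single
R1_pre (their averaging masks are unknown), so the package asserts
volume × concentration = amount but never T1↔C consistency.
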