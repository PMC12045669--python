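# lungquant

Quantitative analysis of contrast-enhanced ultra-short-echo-time (UTE) lung
MRI: where did an intratracheally instilled surfactant + gadolinium bolus
end up, and how much of it is where?

Surfactant replacement by thin catheter (LISA) is standard care for preterm
respiratory distress, yet how the liquid distributes through the lung is
essentially invisible to the clinician. Doping the surfactant with a
Gd-based contrast agent and imaging with a 3D UTE sequence before and after
instillation makes the liquid visible; this package turns those images into
quantitative maps and regional statistics. It is a library for imaging
scientists working with such protocols (or validating them in silico), with
a thin CLI for file-driven runs.

## Model

The UTE spoiled-gradient magnitude signal at flip angle α, repetition time
TR and longitudinal relaxation time T1 is

    S = A · sin α · (1 − E1) / (1 − cos α · E1),    E1 = exp(−TR/T1)

with A a scanner/proton-density scale constant (TE ≈ 0.1 ms, so T2* decay
is neglected). The pipeline follows the acquisition protocol:

1. **Calibration** — mean signals from a solution-free distal-lung ROI,
   acquired pre-contrast at four flip angles (5°, 8°, 16°, 25°; TR =
   3.7 ms), are jointly fitted for (A, R1_pre): linearized solve
   (S/sin α vs S/tan α), refined by nonlinear least squares.
2. **Mapping** — the post-contrast 25° volume is inverted voxel-by-voxel
   for T1, giving R1_post = 1000/T1 in s⁻¹; out-of-domain voxels
   (S ≥ A·sin α) are flagged, not silently used.
3. **Concentration** — the linear relaxivity relation
   C = (R1_post − R1_pre)/r1, with r1 = 3 mM⁻¹s⁻¹ per Gd³⁺ ion. Because
   concentrations are in mM and voxel volumes in mL, amounts integrate
   directly in µmol.
4. **Regions & metrics** — the lung is partitioned into TLV (total lung
   volume), PER (peripheral enhanced region) and CER (central enhanced
   airways; the complement of PER within the enhancement). The headline
   metrics are PDF = 100·Q(PER)/(Q(PER)+Q(CER)) (amount partitioning) and
   PVF = 100·vol(PER)/vol(TLV) (spatial reach), plus slice-wise anatomical
   profiles and maximum-intensity projections.

Because no scanner data ship with the package, a **digital thorax phantom**
(`lungquant.phantom`) provides the test substrate: ellipsoidal lungs, a
four-generation airway tree whose inner walls the instillate coats over a
thin shell, dorsally pooling peripheral blobs (supine, gravity-dependent),
a known total Gd amount, and multi-flip-angle volumes rendered through the
same signal equation with seeded noise.

## Worked example

`python examples/02_phantom_recovery.py` images the default thorax at
peripheral SNR 50 and runs the full chain with ground-truth masks:

```
calibration: A = 1000.9, R1_pre = 1.2475 1/s
metric                           truth   recovered
Gd amount (umol)                100.00       99.90
PDF (%)                          84.00       84.01
PVF (%)                          32.95       32.95
mean concentration (mM)           3.07        3.06
mean T1 post (ms)               104.81      105.00
```

The instilled 100 µmol and the 84% peripheral amount fraction are recovered
to well under a percent at this noise level. `examples/01_…` walks the
signal model and the VFA fit; `examples/03_…` shows ventral-to-dorsal
profiles (dorsal pooling) and the cohort summary statistics. A minimal
file-driven run:

```
lungquant phantom --out ph --seed 1        # synthetic dataset + truth
lungquant demo --n 3 --snr 50              # phantom cohort -> summary table
```

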