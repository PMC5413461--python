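# Methods

This note documents the models behind each stage of the synthetic
pipeline, the defaults and why they hold, and what the simulations do and
do not establish about real data.

## Digital phantoms

**Bone sample.** An inverted-U of cortical bone (outer span 8 mm, height
and depth 8 mm, limbs 1.5 mm thick) rests with its open side down on a
saline cylinder (radius 6 mm) whose top touches the base of the U; a
plastic spacer sits in the cavity. The grid is 96³ at 0.5 mm so the
1.5 mm limbs fall exactly on voxel boundaries; labels are assigned by 3³
supersampling with a majority rule, keeping voxelized volumes within a
few percent of the closed forms (the U volume is exact).

**Rat head.** Concentric ellipsoids on a 64³, 0.7 mm grid: a head of
20 × 20 × 25 mm (z the long axis), from outside in a 2 mm muscle layer, a
0.7 mm cortical-bone skull shell, and the brain, which carries uniform
activity (100 arb/mL). A soft-tissue neck cylinder (radius 10 mm) and a
ventral jaw block attach the head to the grid boundary; they stand in for
the jaw musculature, tongue and skin a real head carries. An optional
ventral gap in the shell emulates the skull-base signal dropout of
surface-coil acquisitions; it is off by default. A shell thinner than one
voxel is accepted with a recorded partial-volume warning.

**Composition.** Bone mineral carries ³¹P at
3 × 3800 g/L ÷ 402 g/mol = 28.36 mol/L (hydroxyapatite density and molar
mass per three phosphorus). Mobile ³¹P (PCr + ATP + Pi lumped): brain
15 mmol/L (physiological); muscle and neck/jaw soft tissue share an
*effective* 86.7 mmol/L. That value is calibrated, in closed form, so the
whole-head spectrum has a 7 % liquid fraction under the default timing:
with saturation ratio r = ss(T1=2 s)/ss(T1=20 s) = 1.82 at the bone Ernst
angle, the mobile moles must satisfy
M_l = 0.07/(0.93 · r) · M_b, and the phantom's soft-tissue volume fixes
the concentration. It is deliberately above tissue-by-tissue physiology
because the two-compartment head under-represents real soft-tissue volume
and surface-coil proximity weighting; it is an effective spectroscopic
parameter, not a claim about muscle chemistry.

**Ground-truth attenuation.** Air 0; all soft tissues water-equivalent,
μ = 0.096 cm⁻¹ at 511 keV; cortical bone and plastic are *defined* by
pushing their CT numbers (500 HU, 120 HU) through the default bilinear
model — 0.12606 cm⁻¹ for bone — so a noiseless CT pipeline reproduces
μ_true identically. 500 HU is low for adult human cortical bone but
defensible for a thin rodent calvarium, and makes k·SNR consistency hold
(0.0042 × 30 ≈ 0.126).

## ³¹P signal model

Spoiled steady state: s = sin θ (1−E)/(1−E cos θ), E = exp(−TR/T1). At
TR 15 ms the default flip is the bone Ernst angle,
arccos(E) = 2.22°. Bone T1 = 20 s, liquid T1 = 2 s (≈10× shorter), bone
T2* = 85 μs (Lorentzian FWHM 1/(πT2) = 3.74 kHz = 18.5 ppm at 202.4 MHz),
liquid T2* = 10 ms.

**Spectrum.** One broad Lorentzian at 0 ppm (area ∝ total apatite moles ×
bone saturation) plus sharp lines at −2.5, −5.0, −10.0 and −18.8 ppm
(area ∝ total mobile moles × liquid saturation, split 0.4/0.2/0.2/0.2
across PCr and the three ATP phosphates, Pi folded into the first
weight). Areas are width-independent, so the total integral is conserved
under T2* changes; the default axis spans ±800 ppm because the broad
line's tails carry ~1 % of its area even there. `liquid_fraction` fits
the broad component as a single Lorentzian (center within ±2 ppm, width
8–60 ppm) on the spectrum outside ±2 ppm bands around the liquid shifts,
and reports clipped-residual band area over (band area + analytic broad
area). The width bounds keep the fit from latching onto sharp lines when
no broad component exists.

**Imaging, image-domain fidelity (default).** Effective signal density =
apatite × bone saturation + mobile × liquid saturation, each multiplied
by its mean within-readout T2* decay, T2*/T·(1−e^(−T/T2*)) with
T = 64/250 kHz = 256 μs (0.32 for bone, ~0.99 for liquid) — an amplitude
approximation to the k-space filter the decay really is. A sinc
excitation weight |sinc(f τ)| is applied with f = radius ×
(bandwidth/FOV) = 2.79 kHz/mm, isotropized over spoke directions; an
optional exponential surface-coil depth profile is off by default. The
density is blurred with a Gaussian PSF of FWHM one nominal voxel
(89.6 mm/64 = 1.4 mm), sampled onto the ZTE grid, and complex Gaussian
noise of sd noise_sd/√n_averages is added before the magnitude (Rician
statistics; pure background then has mean SNR √(π/(4−π)) ≈ 1.91).

**Imaging, k-space fidelity.** Half-projections along a deterministic
Fibonacci-sphere direction set; samples interpolated from a 2×
oversampled FFT of the object (a controlled approximation to the analytic
transform); trilinear gridding with weight normalization; Gaussian
apodization matched to the one-voxel PSF; inverse FFT. On a 32³ head the
two fidelities agree to 6–7 % RMS of the peak in-object signal
(noiseless), the residual being streak/undersampling structure.

**Noise calibration.** The channel noise sd of each preset is set by a
noiseless simulation so that the *measured* mean bone-mask SNR equals the
in-study value: 30 for the bone sample at 96 averages, 10 for the skull
at 16 averages. This pins the synthetic experiments to the regime the
method actually operated in; SNR then scales as √(averages) exactly by
construction.

## CT and HU→μ

CT is simulated in image space: material HU (air −1000, water/saline 0,
soft tissue 40, bone 500, plastic 120), Gaussian blur to the requested
resolution (default 0.86 × 0.86 × 0.796 mm), resampling to the CT grid,
20 HU Gaussian noise. The bilinear conversion uses
μ = 0.096·(HU+1000)/1000 below 47 HU and a bone branch of slope
5.64 × 10⁻⁵ cm⁻¹/HU above, intercept fixed by continuity; it is
continuous, monotone and clipped to [0, 0.3] cm⁻¹. The parameterization
is configurable since vendors differ in dialect.

## Calibration (SNR → μ)

SNR maps divide the magnitude image by the sd of a corner background ROI
(≥100 voxels, disjoint from the object). The conversion factor is the
**mean of voxelwise μ/SNR ratios** over a bone mask (CT > 300 HU), with
an SNR floor of 3 to prevent ratio blow-up; a zero-intercept regression
slope is available as a cross-check estimator. The estimation runs on the
CT grid — native-resolution μ with the smooth SNR field interpolated up —
because point-resampling a sharp 1.5 mm structure onto the 1.4 mm ZTE
grid collapses its values. Defaults give k = 0.0045 ± 0.0004 cm⁻¹ per
unit SNR (the dispersion is the voxel-ratio sd, reported like a
measurement spread). k is tied to the calibration scan duration
(TR × 13030 × 96 = 18763 s); SNR from other durations is scaled by
√(t_ref/t_acq) before use.

**μ-maps.** *CT-AC*: bilinear conversion of the simulated CT, resampled
to the PET grid, with μ < 0.005 cm⁻¹ clamped to zero in air. *NoBone-AC*:
0.096 cm⁻¹ everywhere inside the head mask (bone treated as soft tissue).
*31P-AC*: NoBone + k·SNR, where the SNR floor (default 5) is applied in
the **as-acquired** domain before √time normalization — after ×√6
upscaling a fixed floor would pass ~40 % of the Rayleigh background,
flooding the map, whereas the acquired-domain floor passes ~0.5 %
(isolated "red spots", as seen in practice). The additive construction
double-counts soft-tissue μ inside skull voxels; a replace-style variant
can be built from the same pieces but the additive map is the method as
defined.

## PET simulation and OSEM

2D parallel beam per transaxial slice: 96 angles over [0, π) (96 rather
than 90 so the default 4 subsets divide evenly), radial bins at the voxel
pitch. The projector is an explicit sparse matrix — pixel-driven with 3×3
sub-pixel sampling (suppressing the Moiré ripple of center-only
pixel-driven projection; disk projections match analytic chords within
2 %) — so forward and back projection are exact adjoints. Counts are
Poisson with mean ∝ projected activity × exp(−∫μ_true dl), scaled to
2 × 10⁶ expected events per slice stack. OSEM uses survival-weighted
(1/ACF) forward and back projections, 4 subsets × 8 iterations, uniform
initialization, no post-filter; with one subset it is exactly MLEM and
inherits EM's likelihood ascent. Scatter, randoms, arc, decay and
normalization corrections are identity because those effects are not
simulated; FORE is unnecessary because 2D slices are generated directly.

## Metrics

The peripheral-brain ROI is the outermost 2-voxel rim of the brain mask
(erosion difference), the region most sensitive to skull attenuation.
Comparisons report per-method ROI statistics, percent differences vs
CT-AC, and Welch t-tests (the pooled-variance variant is available).

**Skull Dice rule.** For a 0.7 mm shell imaged at 1.4 mm (ZTE) and
0.86 mm (CT), fixed absolute thresholds produce masks of incomparable
thickness, so the experiment uses the standard thin-structure
delineation: the CT is first smoothed so its *total* resolution (PSF ⊕
voxel footprint, in quadrature) matches the ZTE total resolution
(1.69 mm); the SNR map is resampled onto the CT grid; each image is
thresholded halfway between its background (median SNR; 40 HU) and its
skull peak (99.8th percentile); the largest connected component is kept.
The rule's realized thresholds are recorded in every report. Defaults
give Dice = 0.900 ± 0.003 over seeds.

## What the synthetic experiments show — and don't

The generator reproduces the *mechanisms*: concentration and saturation
contrasts, √time SNR scaling, partial-volume dilution of a thin shell,
Rician noise, attenuation physics, and the qualitative AC ordering
(NoBone < CT < 31P in the peripheral ROI, 10/10 seeds at default count
levels). It does not model coil-loading differences between sample and
head, chemical differences between bovine and rat bone, eddy currents or
FID truncation, scatter/randoms, anatomical realism of the skull base and
jaw, or registration error (transforms are known in simulation; the
intensity-based rigid estimator exists to exercise the step). Passing
tests therefore validate the pipeline's internal consistency and the
stated numerical behaviors at desk scale, not in-vivo performance.

## Problem sizes and numerical choices

Default grids (64³ head at 0.7 mm, 96³ sample at 0.5 mm, 96-angle
sinograms, 2 × 10⁶ counts, 10-seed sweeps) were chosen so a full
experiment runs in seconds and the whole suite in about a minute on one
CPU. Degenerate inputs fail loudly (empty masks, zero activity, zero
noise sd, non-dividing subsets); EM updates guard denominators at 1e−12;
μ-maps are clipped to physical ranges ([0, 0.25] cm⁻¹ for μ_31P,
[0, 0.3] overall). All randomness flows from explicit seeds; the
experiment runner derives per-stage seeds from one master seed by a CRC
scheme, and every artifact records (config hash, seed, stage).
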