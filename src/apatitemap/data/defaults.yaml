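# Default physical constants and composition of the synthetic phantoms.
#
# Provenance tags:
#   [printed]  value printed in the source study's methods/discussion
#   [standard] standard literature value for the quantity
#   [derived]  computed from other entries (derivation in docs/methods.md)
#   [model]    modeling choice of this package (rationale in docs/methods.md)

physics:
  mu_water_511_cm: 0.096          # [standard] water linear attenuation at 511 keV
  hu_breakpoint: 47.0             # [standard] bilinear HU->mu soft/bone breakpoint
  hu_bone_slope: 5.64e-05         # [standard] bone-branch slope, cm^-1 per HU
  hydroxyapatite_density_g_per_l: 3800.0      # [printed] mineral density of bone apatite
  hydroxyapatite_molar_mass_g_per_mol: 402.0  # [printed] per three phosphorus atoms
  hydroxyapatite_p_per_formula: 3             # [printed]
  p31_larmor_mhz_11p7t: 202.4     # [standard] 31P Larmor frequency at 11.7 T

# Material Hounsfield units assigned by the CT simulator. [model] except the
# HU scale anchors (air -1000, water 0) which are definitional.
hounsfield:
  air: -1000.0
  saline: 0.0
  soft_tissue: 40.0
  muscle: 40.0
  brain: 40.0
  cortical_bone: 500.0   # [model] thin rodent calvarium, sub-adult-cortical HU;
                         # chosen so the bilinear conversion returns mu_bone
  plastic: 120.0         # [model] acrylic-like spacer

# Ground-truth 511-keV attenuation. Soft tissues are water-equivalent; the
# bone and plastic values are DERIVED by pushing their HU through the default
# bilinear model so that a noiseless CT pipeline reproduces mu_true exactly.
mu_true:
  air: 0.0
  water: 0.096           # [standard]

# Targets for the noise-level calibration of the two ZTE presets: the complex
# channel noise sd is set, per phantom, so the mean bone-mask SNR of a
# simulated run matches the corresponding measured value. [printed]
snr_targets:
  bone_sample: 30.0
  rat_head_skull: 10.0

composition:
  # 31P content of bone mineral: 3 * 3800 / 402 = 28.358 mol/L  [derived]
  apatite_p31_mol_per_l: 28.3582
  # Mobile (liquid-state) 31P, lumped PCr+ATP+Pi per tissue, mmol/L.
  # Brain is physiological [standard]; muscle / head soft tissue is an
  # EFFECTIVE value calibrated so the whole-head spectrum has a 7% liquid
  # fraction under the default geometry — it lumps soft tissue that the
  # simplified head model does not represent explicitly (jaw musculature,
  # tongue, skin, marrow) and surface-coil proximity weighting. [derived]
  mobile_brain_mmol_per_l: 15.0
  mobile_muscle_mmol_per_l: 86.7
  mobile_soft_tissue_mmol_per_l: 86.7
  # Fraction of total head 31P signal contributed by liquid-state species,
  # used to calibrate the effective mobile concentration. [printed]
  target_liquid_fraction: 0.07

spectrum:
  # Chemical shifts (ppm) of the sharp liquid-state lines and the fixed area
  # split of the mobile pool across them (PCr and the three ATP phosphates;
  # inorganic phosphate is folded into the PCr weight). [printed shifts /
  # model weights]
  sharp_shifts_ppm: [-2.5, -5.0, -10.0, -18.8]
  sharp_weights: [0.4, 0.2, 0.2, 0.2]
  broad_center_ppm: 0.0   # [model] bone line referenced to 0 ppm
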