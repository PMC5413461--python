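# apatitemap

A fully synthetic, desk-scale pipeline for **PET bone attenuation
correction from ³¹P zero-echo-time (ZTE) MRI of hydroxyapatite**.

## The problem

PET quantification requires correcting each line of response for photon
attenuation, `ACF = exp(+∫ μ dl)`, where μ is the 511 keV linear
attenuation coefficient. On PET-MRI systems the skull is the hard part:
¹H-MRI cannot see the mineral phase of cortical bone, so MR-based
attenuation maps either neglect bone (underestimating activity near the
skull) or guess it from atlases. Hydroxyapatite, Ca₅(PO₄)₃OH, contains
three ³¹P nuclei per formula unit at ~30 mol/L in bone mineral — a
thousandfold more than the mmol/L liquid metabolites (PCr/ATP) — and is
detectable by ZTE MRI despite its ~85 μs T2. The method simulated here:

1. **Calibration** — image a cortical-bone sample with ³¹P-ZTE and CT;
   convert the ZTE image to SNR (voxel value / background noise sd) and
   the CT to μ via the standard bilinear HU→μ relationship; estimate the
   conversion factor `k = mean(μ / SNR)` over bone voxels.
2. **In vivo** — acquire ³¹P-ZTE of a rat head, convert to SNR, correct
   for acquisition time (SNR ∝ √t), and form a bone term
   `μ_31P = k · SNR`. Reconstruct the same PET data with three
   attenuation maps: CT-based (*CT-AC*, gold standard), soft-tissue-only
   (*NoBone-AC*, Dixon-like), and soft tissue + μ_31P (*31P-AC*).

Everything — phantoms, spectra, ZTE/CT/PET acquisitions, OSEM
reconstruction, metrics — is generated from seeded digital phantoms; no
external data are required.

## Worked example

```bash
apatitemap run --out runout --seed 1
```

runs the full protocol (bone-sample calibration, in-vivo ZTE + CT + PET,
three OSEM reconstructions, metrics) in well under a minute and prints:

```
   method  roi_mean    roi_sd  n_voxels  pct_diff_vs_ref     p_vs_ref
    CT-AC 54.545237 13.075306      2480         0.000000          NaN
NoBone-AC 53.864796 12.930701      2480        -1.247480 6.543481e-02
   31P-AC 58.058786 13.860661      2480         6.441531 6.051570e-20
ordering: expected; Dice(31P, CT) = 0.902
```

Reading this: ¹⁸F activity in a peripheral-brain ROI (2-voxel rim of the
brain, 2480 voxels) is **underestimated by ~1.2 % when bone is neglected**
and **overestimated by ~6 % by the ³¹P-based correction** relative to
CT-AC — the ³¹P map adds μ_31P on top of the soft-tissue map (double
counting soft tissue inside skull voxels) and spreads bone over the ZTE
point spread. The skull masks segmented from the ³¹P-ZTE and CT images
overlap with a **Dice index of 0.90**. The calibration stage
(`runout/calibration.json`) reports
`k = 0.0045 ± 0.0004 cm⁻¹ per unit SNR` from 168 bone voxels. The small
bone effect (~1 %) is expected at rat-head scale, where two 0.7 mm skull
walls add <1 % attenuation on a central line of response.

Intermediates are written as NIfTI volumes with JSON sidecars, plus
fusion overlays, a three-panel PET comparison and an ROI bar chart under
`runout/figures/`. Each pipeline stage is also available as its own
subcommand (`apatitemap phantom|zte|ct|calib|pet ...`), and as library
functions (`apatitemap.run_experiment`, module APIs).

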