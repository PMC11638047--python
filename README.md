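# dcequant

Quantitative dynamic contrast-enhanced (DCE) MRI analysis for predicting
breast-cancer response to neoadjuvant chemotherapy (NAC), built for
researchers evaluating pharmacokinetic (PK) imaging biomarkers across
scanner platforms.

The package implements the full analysis chain:

* **B1-corrected variable-flip-angle (VFA) R1 mapping** — voxelwise
  nonlinear fitting of the SPGR signal equation
  `S(α) = S0 (1 − E) sin α / (1 − E cos α)`, `E = exp(−TR·R1)`, with
  per-voxel flip-angle correction from a B1 ratio map and vendor
  scale-factor correction.
* **PK modeling** of the dynamic series with the Tofts model (TM,
  fast-exchange limit) and the shutter-speed model (SSM, fast-exchange
  regime with finite transcytolemmal water exchange rate k_io), driven by a
  Parker-style population arterial input function. Tissue kinetics follow
  `C_t(t) = K^trans ∫ C_p(τ) e^{−k_ep(t−τ)} dτ`, `k_ep = K^trans/v_e`; the
  SSM observed relaxation rate is the smaller eigenvalue of the two-site
  water-exchange matrix. Fits run per voxel or on the ROI-average curve,
  with fixed (0.60 s⁻¹) or VFA-measured R1,0 — the four analysis conditions
  whose comparison the package automates.
* **Bolus arrival time** alignment via a linearized-Tofts coarse-grid
  search with derivative-free refinement.
* **Semi-quantitative maps and QC** — signal enhancement ratio
  SER = (S9 − S2)/(S26 − S2), unenhanced-voxel masking, plausibility
  filtering of k_io to 0.1–20 s⁻¹, time-summed EES concentration Σ[CA_o]
  maps, and per-tumor histogram summaries (mean, median, iqr).
* **Response statistics** — per-patient percent changes (V21%, V31%),
  Wilcoxon rank-sum group comparison, paired t-tests between analysis
  approaches, and univariate-logistic ROC AUC with DeLong 95% CIs for
  pCR vs non-pCR prediction.
* **A synthetic digital-reference-object cohort** (ground-truth parameter
  maps, DCE + VFA + B1 volumes, ellipsoidal multi-slice ROIs, group-
  dependent longitudinal treatment effects, Rician noise) so the entire
  chain is testable without patient data.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import numpy as np
from dcequant import (AcquisitionProtocol, CohortDesign, default_aif,
                      fit_ssm, fit_tm, generate_truth_maps,
                      roi_average_curve, simulate_dce_series)

protocol = AcquisitionProtocol()          # 32 frames x 15 s, FA 10 deg
aif = default_aif(protocol)               # bolus at the 3rd frame

design = CohortDesign(n_voxels=100, seed=0)
truth = generate_truth_maps(design, patient_index=0, visit="V1")
dce = simulate_dce_series(truth, protocol, aif, noise_sigma=0.02, seed=0)

curve = roi_average_curve(dce, truth.roi_mask)
tm = fit_tm(curve, r10=0.60, aif=aif, protocol=protocol)
ssm = fit_ssm(curve, r10=0.60, aif=aif, protocol=protocol)
print(f"TM : Ktrans {tm.ktrans:.3f} min^-1  ve {tm.ve:.3f}")
print(f"SSM: Ktrans {ssm.ktrans:.3f} min^-1  ve {ssm.ve:.3f} "
      f"kio {ssm.kio:.2f} s^-1")
```

prints

```
TM : Ktrans 0.161 min^-1  ve 0.296
SSM: Ktrans 0.254 min^-1  ve 0.425 kio 1.63 s^-1
```

The tumor was simulated with shutter-speed (finite water exchange)
kinetics around median K^trans 0.25 min⁻¹, v_e 0.4, k_io 2 s⁻¹: the SSM
recovers the ROI-level parameters, while the TM — which assumes infinitely
fast water exchange — underestimates K^trans by ~35%, the systematic
TM-vs-SSM gap this analysis is designed to expose.

The same chain runs from the shell:

```
dcequant simulate --config cfg.yaml --outdir cohort/
dcequant relaxometry --manifest cohort/P00_V1_manifest.json --out r1.nii
dcequant fit --manifest cohort/P00_V1_manifest.json --model ssm \
         --mode voxel --r10 fixed:0.6 --out maps/
dcequant maps --manifest cohort/P00_V1_manifest.json --outdir maps/
dcequant run-all --config cfg.yaml --outdir results/
dcequant stats --summary results/summary.csv \
         --metric ssm_ktrans_iqr_voxel_fR10 --change V31%
```

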