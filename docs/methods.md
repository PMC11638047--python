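# Methods

`dcequant` implements the quantitative analysis chain used to predict breast
cancer response to neoadjuvant chemotherapy (NAC) from dynamic
contrast-enhanced (DCE) MRI, and a synthetic digital-reference-object (DRO)
cohort generator that exercises every stage against known ground truth.

## Signal model

All acquisitions are spoiled gradient-recalled echo (SPGR). The steady-state
signal at flip angle α and repetition time TR is

    S(α) = S0 (1 − E) sin α / (1 − E cos α),   E = exp(−TR · R1).

`relaxometry.spgr_signal` evaluates this closed form; its inverse (used to
convert a measured dynamic curve to concentration at fixed R1,0) clips the
recovered rate to [1e−4, 50] s⁻¹ so that noise excursions outside the
physically attainable signal range do not produce infinities.

### VFA R1,0 mapping with B1 correction

Native tissue R1 (R1,0 = 1/T1,0) is mapped from variable-flip-angle (VFA)
data at nominal angles 3°, 9°, 15°. Per voxel, the nominal angles are
multiplied by the B1 ratio map (actual/prescribed flip angle; 1.0 = perfect
calibration) and (R1, S0) are fitted by bounded nonlinear least squares
(R1 ∈ (0, 20] s⁻¹, tolerances 1e−12, ≤200 evaluations), seeded by the
DESPOT1 linearization (S/sin α vs S/tan α). On noiseless consistent data the
linear seed and the refined fit agree to <0.1% and recovery is exact to
machine precision; the fit is invariant to overall intensity scale.
Per-angle vendor intensity scale factors, when present, are divided out
first (`apply_scale_correction`).

Voxels with all-zero/non-finite signals or failed convergence are flagged
invalid, never dropped silently. A B1 *miscalibration* scenario — excitation
delivered at a factor f of nominal while the emitted map claims 1.0 — biases
the fit: f < 1 inflates R1 (f = 0.7 gives ≈ +105% on a 0.6 s⁻¹ tissue,
reproducing the ≥100% overestimation failure mode observed on one scanner
platform), f > 1 deflates it (f = 1.2 → ≈ −31%). The pipeline flags a
measured R1,0 map invalid when the ROI median falls outside a plausible
breast-tissue range (0.25–1.1 s⁻¹) and excludes such patients from
measured-R1,0 analysis conditions only.

## Pharmacokinetic models

Tissue contrast-agent concentration follows the Kety/Tofts rate law

    C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ,   k_ep = K^trans / v_e,

with K^trans in min⁻¹ (converted internally to s⁻¹), v_e ∈ (0, 1]. The
convolution is computed exactly for the piecewise-linear interpolant of the
arterial input function (AIF) on a uniform 1 s grid via the one-pole
recursion y_{k+1} = E y_k + I_k (scipy.signal.lfilter), with
series-stabilized coefficients for small k_ep·Δt. Against the boxcar-AIF
closed form v_e (1 − e^(−k_ep t)) the numeric result agrees to ≈1e−15;
doubling the grid spacing changes C_t by <0.5%.

**AIF.** A measured per-patient AIF is unavailable; the Parker (2006)
population form — two Gaussians plus a sigmoid-gated exponential washout —
stands in for the population-averaged input, with bolus onset at the start
of the third dynamic frame (t = 30 s on the default grid). The parametric
output is used directly as plasma concentration (no hematocrit rescaling);
since the AIF scale multiplies K^trans linearly, it cancels in the percent
changes that carry the response prediction.

**Tofts model (TM, fast-exchange limit).** R1(t) = R1,0 + r1 · C_t(t):
transcytolemmal water exchange is assumed fast enough that relaxation stays
mono-exponential at the population-average rate.

**Shutter-speed model (SSM, fast-exchange regime).** Finite cellular water
efflux rate k_io makes two-site (intra-/extracellular) longitudinal
relaxation bi-exponential. The observed rate is the smaller eigenvalue of
the exchange matrix,

    R1 = ½[R1i + k_io + R1o(t) + k_oi]
         − ½ √([R1i + k_io − R1o(t) − k_oi]² + 4 k_io k_oi),

with R1o(t) = R1o,0 + r1 C_t(t)/v_e, water populations p_o = v_e,
p_i = 1 − v_e (water-density corrections omitted), detailed balance
k_oi = k_io p_i / p_o, and r1i = r1o,0 = R1,0 before contrast (no
compartmental difference pre-contrast — required for the fixed-R1,0
convention to be well defined). As k_io → ∞ this converges (at rate 1/k_io)
to the population-weighted FXL rate; at k_io = 1e4 s⁻¹ agreement is <1e−4
relative over tumor-relevant v_e ∈ [0.4, 1], C_t ∈ [0, 0.5] mM.

**Relaxivity.** r1 = 4.0 mM⁻¹ s⁻¹ (3T gadoteridol literature), configurable.
It scales absolute concentrations only and cancels in percent changes.

## Fitting

Per voxel (or per ROI-average curve) the forward model Kety → R1(t) → SPGR
is fitted by bounded trust-region least squares on the signal directly; the
signal scale S0 is calibrated so modeled pre-injection frames match the
measured baseline mean exactly (frames 1–2 on the default grid; frame 1 can
be excluded by configuration for sequences whose first frame differs).

* TM: (K^trans, v_e), bounds [0, 5] min⁻¹ × (1e−3, 1], single start.
* SSM: (K^trans, v_e, k_io), k_io ∈ (1e−3, 1000] s⁻¹ — the generous ceiling
  keeps exchange-insensitive fits from stopping at a realistic boundary
  prematurely. Three fixed starts (deterministic multi-start) mitigate local
  minima; the lowest-residual solution is kept. A fit landing within 1% of
  any bound is flagged `at_bound`; exchange-insensitive (FXL-like) curves
  deterministically drive k_io to the 1000 s⁻¹ ceiling.

k_ep = K^trans/v_e is derived exactly in every fit result.

**Bolus arrival time (BAT).** The AIF is aligned to a tissue curve by
minimizing, over a time shift δ, the residual of the linearized Tofts system
C_t = K^trans ∫C_p − k_ep ∫C_t solved by linear least squares on
concentration-converted data (SPGR inversion at fixed R1,0). The cumulative
AIF integral is evaluated on the AIF's own fine grid (the bolus peak is far
sharper than the 15 s frame spacing). A coarse grid of −2 to +6 frame
intervals in ¼-frame steps is scanned, then a bounded derivative-free line
search refines within ±1 coarse step. Noiseless shifts are recovered to
<0.5 s; non-enhancing curves (fractional peak enhancement below the masking
threshold) raise "BAT undefined". The estimator assumes FXL kinetics; on
strongly exchange-attenuated curves it can err by several seconds, which is
why the pipeline estimates one BAT per ROI-average curve rather than per
voxel.

## Maps, masks and summaries

* **Enhancement QC**: a voxel is retained iff (peak post-injection −
  baseline)/baseline ≥ 0.3. The threshold is a declared default (no
  published value exists); it cleanly separates enhancing tumor from the
  non-enhancing background in the DRO.
* **SER** = (S_early − S_base)/(S_late − S_base) with frames 2/9/26 on the
  15 s grid; on other grids the same physical delays (~90 s and ~345 s
  after injection, measured at frame starts) map to the nearest frames.
  Near-zero denominators are flagged invalid. SER is invariant to global
  intensity scaling.
* **k_io filtering**: fitted k_io retained iff 0.1 < k_io < 20 s⁻¹ (strict
  endpoints: at or beyond them the implied intracellular water lifetime is
  implausibly long, or the system is effectively in the fast-exchange
  limit). The retained fraction is reported per tumor over the enhancing
  ROI.
* **Σ[CA_o]**: the time-summed extracellular-space concentration
  Σ C_t(t_k)/v_e · Δt (mM·s; a plain frame-sum mode is available) — a
  surrogate for how much water-exchange information a voxel's curve
  carries. Low-Σ[CA_o] voxels coincide with filtered-out k_io.
* **Histogram summaries**: per-lesion mean, median and iqr (width of the
  interquartile range, q75 − q25) over valid voxels, quantiles by linear
  interpolation of order statistics at 1 + p(n−1); multi-lesion patients
  take the unweighted mean of per-lesion values.

## Response statistics

Percent change of each metric at later visits relative to baseline
(V21%, V31%) is scale-free, so S0/relaxivity/AIF-scale conventions cancel.
Group comparison uses the two-sided Wilcoxon rank-sum test (exact
enumeration for n ≤ 12 without ties, tie-corrected normal approximation
otherwise); method comparisons use paired Student's t. Prediction of
pathologic complete response (pCR) uses univariate logistic regression with
ROC analysis; because the logistic transform is monotone, the ROC of the
fitted probabilities coincides with the concordant-pair (rank; ties =
half-credit) AUC of the raw score, and both routes are computed and checked
for equality. The AUC 95% CI is DeLong (a bootstrap CI was considered and
not implemented; DeLong is standard, deterministic and fast). AUC is
reported in the discriminative orientation (≥ 0.5). Percent changes are
rounded to integers in report tables, full precision retained internally.

## Synthetic cohort generator

The DRO emulates the statistical structure of a 15-patient NAC cohort
(6 pCR / 9 non-pCR by default) scanned at baseline (V1), after the first
NAC cycle (V2) and at the NAC midpoint (V3):

* **Geometry**: one ellipsoidal multi-slice ROI per patient (~500 voxels by
  default) on a regular grid; shape is irrelevant to the analysis math.
* **Baseline truth**: voxel values lognormal around medians K^trans
  0.25 min⁻¹, v_e 0.4, k_io 2 s⁻¹, R1,0 0.6 s⁻¹. The heterogeneity CV
  (default 0.5) applies to K^trans; v_e and k_io use 0.4× and R1,0 0.2× of
  it — perfusion/permeability is the dominant intratumor heterogeneity
  (hot rim / cold core), and this structure is what makes ROI-averaging
  demonstrably dilute the K^trans signal for both PK models.
* **Longitudinal effects**: later visits rescale the same V1 voxel values
  by a group×visit median percent change plus patient-level Gaussian jitter
  and a small voxel-level jitter (CV 0.05). K^trans medians follow the
  published group medians (V2: pCR −71% / non-pCR +1%; V3: −91% / −27%);
  jitter SDs are half the published interquartile widths. Cells with no
  published value (V4, k_io, most v_e entries) are declared assumptions
  consistent with the study's qualitative findings, chosen once.
* **Forward simulation**: per voxel Kety → FXR → SPGR at the default
  protocol (TR 5.6 ms, FA 10°, 32 frames × 15 s, injection at frame 3),
  equilibrium scale S0 = 1000, Rician noise on the magnitude at
  σ = 2% of the median ROI baseline signal (SNR 50); a Gaussian mode exists
  for analytic tests. Pre-injection frames carry baseline signal only.
  An optional per-voxel bolus-arrival jitter (`bat_dispersion_sd`, default
  0) emulates differing transit times; it is off by default so noiseless
  output is the exact aligned forward model.
* **VFA/B1**: VFA signals generated at actual angle = B1 field × nominal;
  the miscalibration mode emits a map of ones regardless of the field.
* Everything is deterministic given (design, seed); seeds for patients,
  visits and noise derive from numpy SeedSequence spawning.

**What the DRO does not emulate** — and hence what passing tests do not
show about real data: breast anatomy and coil shading, fat signal and
suppression artifacts, k-space undersampling/view-sharing reconstruction,
motion and registration error, per-patient AIF variability, biopsy-clip
susceptibility artifacts, and parameter correlations beyond the simple
group-effect structure. Absolute parameter accuracy on real scanners is
not claimed; the DRO validates the estimator chain, not the acquisition.

## Problem sizes used in the shipped analyses

The regression analyses shipped with the package run at reduced size,
chosen as the smallest cohorts that preserve the qualitative structure:
the four-condition ordering comparison uses 3+3 patients × 100 voxels at
V1; the replicated response-prediction experiment uses 100 cohorts of 8+8
patients with ROI-based Tofts fitting at V1/V3 and 60-voxel tumors; noisy
recovery uses 200 replicates of a single voxel. The full 15-patient,
500-voxel, four-visit cohort runs through the same code paths via
`run_pipeline` with the default `CohortDesign`.

## Known limitations

* The FXR expression uses equal pre-contrast compartmental R1 and water
  populations (v_e, 1 − v_e) without density corrections; other
  shutter-speed parameterizations exist.
* The BAT estimator is FXL-based and single-parameter; strongly
  exchange-attenuated or non-enhancing curves are outside its design range.
* ROI- vs voxel-based K^trans ordering is asserted for the default
  heterogeneity structure, not universally: if heterogeneity is dominated
  by v_e/k_io instead of K^trans, the SSM ROI-average fit can exceed the
  voxel mean.
* DeLong CIs degenerate to zero width under perfect separation (reported
  as (1.0, 1.0)), as in the source tables.
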