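# Methods

This note documents the models implemented in cmrkit, the defaults and why
they were chosen, the numerical decisions, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Blood-gas model (`cmrkit.blood_gas`)

Blood oxygen content is the sum of hemoglobin-bound and plasma-dissolved O₂
(μmol O₂ / 100 ml blood):

    [O₂] = Y · Ch(Hct) + pO₂ · Cd

* `Ch` — hemoglobin O₂ carrying capacity, 912 μmol/100 ml at Hct 0.45,
  scaled linearly through zero in hematocrit (Ch ∝ hemoglobin
  concentration). Default Hct: 0.42 (male), 0.40 (female).
* `Cd` — plasma O₂ solubility, 0.138 μmol/100 ml/mmHg.

The saturation curve Y(pO₂) defaults to the one-parameter reference form
`Y = [23400·(pO₂³ + 150·pO₂)⁻¹ + 1]⁻¹`, defined as exactly 0 at pO₂ = 0
(where the expression is 0/0). Its half-saturation pressure is 26.86 mmHg.

**Bohr shift.** CO₂ lowers hemoglobin's O₂ affinity. The `bohr_shifted`
model kind rescales the pO₂ axis by a CO₂-dependent P50:

    log10 P50(pCO₂) = log10 P50_ref + b·(pCO₂ − pCO₂_ref)

with defaults P50_ref = 26.9 mmHg, pCO₂_ref = 40 mmHg, b = 0.0013 /mmHg.
This parametric shift is the shipped stand-in for a full physiological
dissociation model; the `plugin` model kind accepts such a model (e.g. the
NSR Physiome SHbO₂CO₂ equation set) as a registered callable without this
package vendoring its equations. The Bohr-aware kind is the pipeline
default because the analysis it implements is Bohr-aware; the practical
effect on the arteriovenous content difference is below 2% for all
study-like states (tested), so the plain curve is a valid alternative.

**Gas assumptions.** Normoxic conditions: alveolar pO₂ = 104 mmHg converted
to arterial with the clinical alveolar–arterial gradient approximation
AaDO₂ = 2.5 + 0.21·age (mmHg) — the gradient is configurable because this
formula is a documented stand-in, not a measured quantity. Carbogen:
arterial pO₂ assumed 460 mmHg directly (from arterial-line measurements
reported for this stimulus in the literature). Venous pCO₂ = pEtCO₂ + 5
mmHg. Venous pO₂ is obtained by bracketed root finding (Brent, [0, 5000]
mmHg) on the saturation curve, to 10⁻⁶ absolute in saturation.

Not modeled: CO₂ carriage (bicarbonate/Haldane), pH-, temperature- and
2,3-DPG-dependent curve corrections.

## TRUST quantification (`cmrkit.trust`)

The label/control difference signal of venous blood is fit with
`S(eTE) = S0·exp(−eTE/T2)` by nonlinear least squares (log-linear initial
guess, then `scipy.optimize.curve_fit` on the average-collapsed series).
Repeats of a condition are converted to Yv individually and then averaged
at the Yv level. An optional correction removes longitudinal relaxation of
the labeled blood during the eTE (1/T2_blood = 1/T2,app − 1/T1_blood); it
is off by default, matching common TRUST processing.

T2 → Yv uses the quadratic calibration `1/T2 = a1 + a2(1−Y) + a3(1−Y)²`
(rates in 1/s) with coefficients tabulated on an Hct grid {0.35, 0.40,
0.45, 0.50} in a versioned JSON data file (τ_CPMG = 10 ms), linearly
interpolated in Hct. The physiologic root is taken with a small slack
(±0.05 outside [0, 1] clipped); decay rates outside the calibrated range
raise an `ExtrapolationWarning`, and rates below the Y = 1 limit (possible
for noisy measurements of nearly fully saturated blood) are clamped to
Y = 1 under that warning. The pipeline additionally caps venous saturation
at 0.995 before curve inversion so a single extreme subject cannot abort a
cohort run; both events are warned about.

ROI selection takes the k = 4 brightest eTE-0 difference voxels inside a
user-supplied sinus search mask, tie-broken deterministically by voxel
index; the anatomical site (occipital superior sagittal sinus) is the
user's responsibility via the mask.

## pCASL quantification (`cmrkit.asl`)

Single-compartment continuous-labeling closed form at the post-bolus branch
(PLD ≥ ATT): label decays with the blood T1 until arrival and with the
tissue T1 afterwards,

    Q = 2α·T1t·e^(−ATT/T1a)·(1 − e^(−τ/T1t))·e^(−(PLD−ATT)/T1t)
    CBF = 6000·λ·(ΔM/M0)/Q

Defaults: λ = 0.9 ml/g, α = 0.85, τ = 1.5 s, base PLD = 1.7 s, GM tissue
T1 = 1.3 s, GM ATT = 1.3 s, WM tissue T1 = 0.84 s, WM ATT = 1.7 s. Slice
timing of the 2-D readout enters as per-slice PLDs with increment
slice_dt = (TR − PLD − τ)/n_slices = 0.7/17 s by default (configurable; the
acquisition's per-slice increment is rarely reported). Blood T1 is
condition dependent — hyperoxia shortens it — with four bundled
normoxic/hyperoxic scenarios: I 1.65/1.49, II 1.65/1.472, III 1.669/1.527,
IV 1.898/1.743 s (scenario I is the default). Hypercapnia reduces the GM
arrival time by 5%.

Quantification applies GM parameters to every voxel; the resulting WM
underestimation is repaired at the global-averaging step by the
quantification-factor ratio Q_GM/Q_WM (≈ 1.19 at the base PLD for the
defaults). Because this ratio is PLD dependent (it falls by roughly 2% per
slice-time increment: d log(Q_GM/Q_WM)/d PLD = 1/T1t,GM − 1/T1t,WM < 0),
the pipeline applies it per slice (`wm_correction_map`) rather than as one
scalar; the scalar form (`wm_correction_factor`) is retained as the
single-PLD summary. Note the factor *decreases* with WM arrival time:
later-arriving label spends longer relaxing at the slow blood T1 instead of
the fast WM tissue T1, preserving signal.

Global CBF is Σ(pGM·CBF + pWM·CBF·w) / Σ(pGM + pWM) over voxels that are
finite, contain tissue and are not excluded (CSF, cerebellum, brainstem
masks are inputs). Outlier rejection is one pass: voxels with |CBF| >
mean + 2·SD of the included voxel distribution are removed and the weighted
mean recomputed; a symmetric |CBF − mean| > 2·SD variant is available by
configuration. The rejection never removes voxels from a zero-variance map.

**Blood-T1 sensitivity.** For fixed data, quantified CBF scales as
exp(+ATT/T1a), so perturbing the assumed T1a by δ changes CBF — and, by
linearity of CMRO₂ in CBF, CMRO₂ — by `exp(ATT·(1/(T1a(1+δ)) − 1/T1a)) − 1`.
At T1a = 1.49 s and ATT = 1.3 s, δ = +5% gives −4.07% and δ = −5% gives
+4.70%. Re-quantifying the same data under the four T1 scenarios leaves the
normoxic-hypercapnic CBF change essentially unchanged (< 1 pp; the normoxic
T1 nearly cancels between numerator and baseline) and moves the carbogen
change by up to ~3 pp through the scenarios' hyperoxic-T1 spread — small
against the ~9 pp between-subject SD of such changes.

## CMRO₂ assembly and statistics (`cmrkit.pipeline`)

OEF = ([O₂]a − [O₂]v)/[O₂]a, clipped to [−0.05, 1] with a warning (slightly
negative extractions can arise from measurement noise under strong
hyperoxia). CMRO₂ = CBF·([O₂]a − [O₂]v)/100 μmol/100g/min; a negative
arteriovenous difference is flagged but returned.

Three plasma modes quantify the role of dissolved O₂: `full` (default),
`ignore_venous_plasma`, `ignore_all_plasma`. On carbogen-like states the
arterial plasma term (460 × 0.138 ≈ 63 μmol/100 ml) dominates the
difference between modes: ignoring all plasma moves the carbogen CMRO₂
change by well over 10 pp, while ignoring only the venous plasma moves it
by under 2 pp.

**Averaging order matters and is fixed deliberately:** percent changes are
computed per subject against that subject's *preceding* room-air block, and
the per-subject percents are then averaged (mean of percents, not percent
of means — for the toy cohort {50→55, 60→72} these are 15.0% vs 15.45%).
Group statistics are two-sided paired t-tests at α = 0.05 with no
multiple-testing correction; zero-variance pairs are flagged degenerate
rather than tested. A Shapiro–Wilk normality diagnostic is available.
Outputs are deterministic TSV tables plus a JSON provenance block.

## Synthetic data (`cmrkit.synth`)

The generator emulates a 10-subject study (exactly 7 M / 3 F at n = 10,
age ~ N(29.4, 3.4)) with draws truncated to physiologic ranges by
resampling:

| quantity | distribution |
|---|---|
| baseline CBF | N(54.9, 8.2) ml/100g/min |
| baseline Yv | N(0.673, 0.036) |
| baseline pEtCO₂ | N(45.0, 3.6) mmHg; room-air 2 shifted −1.3 mmHg |
| ΔpEtCO₂ | N(4.2, 1.7) (CO₂ in air), N(4.5, 2.2) mmHg (carbogen) |
| CBF reactivity | N(1.7, 1.5) / N(2.8, 3.2) ml/100g/min/mmHg |
| ΔCMRO₂ | N(−13.4, 13.0) / N(−2.0, 27.0) % vs preceding room-air |
| measured Ya | condition means 98.2–98.9%, SD 0.4–0.6 pp |

Room-air-1 CMRO₂ follows from the drawn (CBF, Yv) through the content
equations; stimulus-condition Yv is then obtained by *inverting* the CMRO₂
equation (root finding parametrized by venous pO₂), so the manifest is
forward-consistent: a noiseless bundle round-trips through the pipeline to
machine precision. Rare draws whose (CBF, CMRO₂) pair admits no physiologic
venous saturation are redrawn; together with the truncation bounds (ΔCMRO₂
within [−60, +80]%) this shifts the realized carbogen mean by about +1 pp
from the configured −2.0 — an accepted property of the truncated generator,
not of the estimator.

TRUST series: S0 = 100 a.u., 3 averages, Gaussian noise SD 2 a.u. per
average (difference-signal SNR ≈ 50, typical of sinus TRUST). ASL phantom:
32×32×17 ellipsoidal brain with a *binary* GM shell and WM core
(WM flow = 0.4 × GM flow), a central CSF ellipsoid (no tissue, excluded)
and two caudal slices flagged as excluded cerebellum/brainstem territory;
M0 = 1000 a.u.; Gaussian noise SD 1 a.u. on ΔM (per-voxel SNR ≈ 5 after
averaging, realistic for pCASL) and 10 a.u. on M0. WM voxels are generated
with WM kinetic parameters so GM-parameter quantification underestimates
them — the bias the WM correction repairs. Noise is Gaussian, not Rician:
difference images at these SNRs are approximately Gaussian, and
magnitude-bias modeling is out of scope. All randomness flows from a single
master seed.

**What the phantom does not emulate** (and hence what passing recovery
tests do not demonstrate about real data): partial-volume mixing at tissue
boundaries, motion and physiological noise structure, arrival-time
heterogeneity and dispersion, macrovascular contamination, B0/B1
inhomogeneity, and registration/segmentation error — segmentation maps and
exclusion masks are taken as perfect inputs.

## Validation at a glance

Computed by the test suite and the acceptance script (never hard-coded):
the WM correction factor (1.19), the ±5% blood-T1 sensitivities
(−4.07%/+4.70%), worked OEF values on group-mean physiology (0.32 room-air,
0.25 CO₂-in-air), CMRO₂ on room-air means within 5% of subject-level
averaging (≈ 147 vs 144.5 μmol/100g/min), the carbogen plasma-mode pattern,
saturation inversion against a 10⁻³ mmHg grid-scan oracle, outlier
rejection against brute-force recomputation, noiseless cohort recovery
(machine precision) and noisy 10-subject recovery (median group-effect
error well under 5 pp over 100 seeds).

## Numerical choices and degenerate inputs

* Curve inversion: Brent on [0, 5000] mmHg, residual checked against 10⁻⁶.
* T2 fit: rate-parametrized; constant or all-non-positive series raise
  `FitError`; the fit is invariant to overall signal scaling.
* Quantification outside the post-bolus branch (PLD < ATT) raises a
  `ValidityError` naming the offending PLD.
* ROI ties broken by ascending voxel index (deterministic).
* M0 voxels at or below threshold are masked to NaN and excluded from the
  global mean.
* Problem sizes in tests (phantom grids of 16²–32²×9–17, 100–500 Monte
  Carlo repeats) were chosen to keep the suite seconds-to-minutes scale
  while leaving the statistical assertions comfortably powered.

## Known limitations

* The T2→Yv calibration coefficients are a bundled table following the
  established bovine-blood calibration form; only self-consistency (forward
  vs inverse) is verifiable here. The data file is versioned so
  site-specific tables can be swapped in.
* The A–a gradient formula is a clinical approximation, configurable.
* The kinetic model is the closed-form single-compartment expression; no
  Bayesian arrival-time fitting, dispersion or macrovascular component.
* Voxel-wise CMRO₂ maps, CVR mapping, calibrated-BOLD M-value modeling,
  registration and segmentation are out of scope.
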