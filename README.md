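# cmrkit

Global cerebral oxygen metabolism (CMRO₂) and oxygen extraction fraction
(OEF) estimation from **TRUST** venous-oxygenation MRI and **pCASL**
cerebral-blood-flow MRI under gas breathing challenges: room-air,
hypercapnic-normoxic ("CO₂ in air", 5% CO₂ / 21% O₂) and
hypercapnic-hyperoxic (carbogen, 5% CO₂ / 95% O₂).

It is written for researchers in quantitative physiological MRI who want a
tested, reusable version of this analysis chain — including the blood-gas
oxygen-content model, the hyperoxia blood-T1 correction and the white-matter
CBF correction — plus a synthetic cohort generator with ground truth for
validating the whole pipeline by parameter recovery.

## The model

Per subject and breathing condition:

1. **Yv from TRUST.** The label/control difference signal of venous blood in
   the superior sagittal sinus decays mono-exponentially over effective echo
   times (0/40/80/160 ms): `S(eTE) = S0·exp(−eTE/T2)`. Blood T2 maps to the
   venous hemoglobin saturation Yv through the calibration
   `1/T2 = a1 + a2(1−Y) + a3(1−Y)²` (τ_CPMG = 10 ms, coefficients
   interpolated in hematocrit).

2. **CBF from pCASL.** The single-compartment continuous-labeling kinetic
   model at the post-bolus branch:
   `CBF = 6000·λ·(ΔM/M0) / Q`, with
   `Q = 2α·T1t·e^(−ATT/T1a)·(1−e^(−τ/T1t))·e^(−(PLD−ATT)/T1t)`,
   slice-specific PLDs, λ = 0.9 ml/g, α = 0.85, condition-dependent blood T1
   (1.65 s normoxic, 1.49 s hyperoxic) and a 5% arrival-time reduction under
   hypercapnia. Global CBF is the GM/WM tissue-probability-weighted mean with
   a WM correction factor (Q_GM/Q_WM ≈ 1.19) and 2-SD outlier rejection.

3. **Blood-gas contents.** `[O₂] = Y·Ch(Hct) + pO₂·Cd` with Ch = 912
   μmol/100 ml at Hct 0.45 (scaled linearly in Hct) and Cd = 0.138
   μmol/100 ml/mmHg. Arterial pO₂ comes from the alveolar value (104 mmHg)
   via an age-dependent alveolar–arterial gradient for normoxic conditions
   and is assumed 460 mmHg for carbogen; venous pO₂ is obtained by inverting
   the hemoglobin saturation curve (Severinghaus, optionally Bohr-shifted by
   venous pCO₂ = pEtCO₂ + 5 mmHg) at the measured Yv.

4. **OEF and CMRO₂.**
   `OEF = ([O₂]a − [O₂]v)/[O₂]a` and `CMRO₂ = CBF·([O₂]a − [O₂]v)/100`
   (μmol/100g/min). Changes are computed per subject against the *preceding*
   room-air block as percent of baseline, then averaged across subjects and
   tested with two-sided paired t-tests.

## Worked example

```python
import cmrkit as ck

bundle = ck.generate_bundle(n=10, seed=7)      # synthetic 10-subject study
result = ck.run_pipeline(bundle)

print(result.condition_table[["condition", "cbf_mean", "yv_mean", "cmro2_mean"]].round(1))
print(result.delta_table[["condition", "d_cbf_pct_mean", "d_cmro2_pct_mean", "cmro2_p"]].round(3))
```

prints (this exact seed):

```
condition  cbf_mean  yv_mean  cmro2_mean
 roomair1      56.4     67.0       150.3
   co2air      61.2     75.8       118.6
 roomair2      52.9     65.8       146.3
 carbogen      65.5     79.2       137.4

condition  d_cbf_pct_mean  d_cmro2_pct_mean  cmro2_p
   co2air           8.424           -20.474    0.002
 carbogen          21.655            -6.759    0.416
```

Reading this: CO₂-in-air raised CBF by ~8% and lowered CMRO₂ by ~20%
(significant, p = 0.002) in this synthetic cohort, while the carbogen CMRO₂
change is smaller and not significant — the estimates track this seed's
ground truth (−20.2% and −8.2%) to within ~0.3 and ~1.5 percentage points.

The same works from the shell:

```bash
cmro2 synth --n 10 --seed 7 --out bundle/     # writes NIfTI + TSV + manifest
cmro2 run --bundle bundle/ --out results/     # writes per-subject/group TSVs
cmro2 asl-quant --deltam dm.nii.gz --m0 m0.nii.gz --pgm pgm.nii.gz \
    --pwm pwm.nii.gz --exclude ex.nii.gz --condition carbogen --scenario I \
    --out cbf.tsv
```

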