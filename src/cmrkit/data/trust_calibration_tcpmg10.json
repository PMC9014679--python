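{
  "version": 1,
  "description": "TRUST T2-to-Yv calibration: 1/T2 [1/s] = a1 + a2*(1-Y) + a3*(1-Y)^2 for venous blood at 3 T, tau_CPMG = 10 ms. Quadratic coefficients tabulated on a hematocrit grid following the established bovine-blood calibration model; linearly interpolated in Hct at use time.",
  "tau_cpmg_ms": 10.0,
  "rate_units": "1/s",
  "hct_grid": [0.35, 0.40, 0.45, 0.50],
  "a1": [5.2723, 6.4360, 7.2203, 7.6250],
  "a2": [0.6900, 0.8600, 1.0300, 1.2000],
  "a3": [56.2835, 59.3760, 61.2315, 61.8500]
}
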