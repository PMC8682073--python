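{
  "model": "Framingham general cardiovascular disease, 10-year, lipid-based",
  "version": 1,
  "terms": ["ln_age", "ln_total_chol", "ln_hdl", "ln_sbp_untreated", "ln_sbp_treated", "smoker", "diabetes"],
  "female": {
    "betas": {
      "ln_age": 2.32888,
      "ln_total_chol": 1.20904,
      "ln_hdl": -0.70833,
      "ln_sbp_untreated": 2.76157,
      "ln_sbp_treated": 2.82263,
      "smoker": 0.52873,
      "diabetes": 0.69154
    },
    "s0_10yr": 0.95012,
    "mean_lp": 26.1931
  },
  "male": {
    "betas": {
      "ln_age": 3.06117,
      "ln_total_chol": 1.12370,
      "ln_hdl": -0.93263,
      "ln_sbp_untreated": 1.93303,
      "ln_sbp_treated": 1.99881,
      "smoker": 0.65451,
      "diabetes": 0.57367
    },
    "s0_10yr": 0.88936,
    "mean_lp": 23.9802
  }
}
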