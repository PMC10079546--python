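{
  "schema_version": 1,
  "comment": "Calibrated default generator configuration. Lesion counts are the published cohort marginals (n=626); clinical and cytogenetic distribution parameters were tuned once so the scored cohort reproduces the published six-category risk mix, and are committed here as data.",
  "n": 626,
  "reference_n": 626,
  "mode": "probabilistic",
  "seed": 0,
  "tp53": {
    "single": 32,
    "two_mutations": 7,
    "mutation_deletion": 16,
    "mutation_cnloh": 12
  },
  "sf3b1_count": 199,
  "sf3b1_5q_frac": 0.09,
  "sf3b1_comut_frac": 0.099,
  "flt3_count": 7,
  "flt3_itd_frac": 0.7,
  "kmt2a_ptd_count": 6,
  "npm1_count": 4,
  "gene_prevalence": {
    "ASXL1": 0.252,
    "SRSF2": 0.158,
    "DNMT3A": 0.161,
    "RUNX1": 0.126,
    "U2AF1": 0.0866,
    "EZH2": 0.0588,
    "CBL": 0.0473,
    "IDH2": 0.0429,
    "NRAS": 0.0362,
    "KRAS": 0.0271,
    "ETV6": 0.0216,
    "BCOR": 0.0435,
    "BCORL1": 0.0247,
    "CEBPA": 0.0123,
    "ETNK1": 0.0075,
    "GATA2": 0.0109,
    "GNB1": 0.0062,
    "IDH1": 0.0127,
    "NF1": 0.0359,
    "PHF6": 0.0248,
    "PPM1D": 0.0192,
    "PRPF8": 0.0112,
    "PTPN11": 0.0153,
    "SETBP1": 0.0252,
    "STAG2": 0.071,
    "WT1": 0.0089
  },
  "cyto_distribution": [
    0.05,
    0.66,
    0.07,
    0.12,
    0.1
  ],
  "background_del5q": 0.04,
  "background_del17p": 0.005,
  "minus7_frac_poor": 0.4,
  "clinical": {
    "hb_mean_by_cyto": [
      11.2,
      10.85,
      9.5,
      8.8,
      8.2
    ],
    "hb_sd": 1.3,
    "hb_min": 4.0,
    "hb_max": 18.0,
    "plt_log_mean_by_cyto": [
      5.2,
      5.0,
      4.7,
      4.4,
      4.0
    ],
    "plt_log_sd": 0.55,
    "anc_log_mean": 0.69,
    "anc_log_sd": 0.7,
    "anc_missing_frac": 0.278,
    "blasts_low_frac_by_cyto": [
      0.9,
      0.8,
      0.45,
      0.2,
      0.05
    ],
    "blasts_low_max": 2.0,
    "blasts_tail_scale_by_cyto": [
      2.5,
      3.0,
      4.0,
      5.5,
      8.0
    ],
    "blasts_max": 19.0
  },
  "vaf": {
    "alpha": 8.0,
    "beta": 14.0,
    "cnloh_mean": 66.0,
    "cnloh_sd": 9.0,
    "cnloh_min": 40.0,
    "cnloh_max": 95.0
  },
  "survival": {
    "h0_os": 0.012,
    "h0_lt": 0.0035,
    "hazard_doubling": true,
    "censor_min": 6.0,
    "censor_max": 228.0,
    "weibull_shape": 1.0
  }
}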