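{
  "schema_version": 1,
  "comment": "IPSS-M variable table. log_hazard holds the published Cox log-hazard coefficient; the score is sum(log_hazard * (x - center)) / ln(2), so one score unit corresponds to a doubling of hazard. best_value/worst_value are the fill-ins used for the best-/worst-case scenarios when a variable is unknown.",
  "cutpoints": [-1.5, -0.5, 0.0, 0.5, 1.5],
  "category_labels": ["VL", "L", "ML", "MH", "H", "VH"],
  "variables": [
    {"name": "CYTOVEC", "kind": "cytogenetic", "gene": null, "log_hazard": 0.287, "center": 1.39, "best_value": 0.0, "worst_value": 4.0, "transform": "cyto_category"},
    {"name": "BLAST5", "kind": "clinical", "gene": null, "log_hazard": 0.352, "center": 0.922, "best_value": 0.0, "worst_value": 4.0, "transform": "blasts_cap20_div5"},
    {"name": "TRANSF_PLT100", "kind": "clinical", "gene": null, "log_hazard": -0.222, "center": 1.41, "best_value": 2.5, "worst_value": 0.0, "transform": "platelets_cap250_div100"},
    {"name": "HB1", "kind": "clinical", "gene": null, "log_hazard": -0.171, "center": 9.87, "best_value": 20.0, "worst_value": 2.0, "transform": "hemoglobin"},
    {"name": "TP53multi", "kind": "gene_main", "gene": "TP53", "log_hazard": 1.18, "center": 0.071, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "MLL_PTD", "kind": "gene_main", "gene": "KMT2A", "log_hazard": 0.798, "center": 0.0247, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "FLT3", "kind": "gene_main", "gene": "FLT3", "log_hazard": 0.798, "center": 0.0108, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "SF3B1_5q", "kind": "gene_main", "gene": "SF3B1", "log_hazard": 0.504, "center": 0.0166, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "SF3B1_alpha", "kind": "gene_main", "gene": "SF3B1", "log_hazard": -0.0794, "center": 0.186, "best_value": 1.0, "worst_value": 0.0, "transform": "binary"},
    {"name": "NPM1", "kind": "gene_main", "gene": "NPM1", "log_hazard": 0.43, "center": 0.0112, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "RUNX1", "kind": "gene_main", "gene": "RUNX1", "log_hazard": 0.423, "center": 0.126, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "NRAS", "kind": "gene_main", "gene": "NRAS", "log_hazard": 0.417, "center": 0.0362, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "IDH2", "kind": "gene_main", "gene": "IDH2", "log_hazard": 0.379, "center": 0.0429, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "CBL", "kind": "gene_main", "gene": "CBL", "log_hazard": 0.295, "center": 0.0473, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "ETV6", "kind": "gene_main", "gene": "ETV6", "log_hazard": 0.287, "center": 0.0216, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "EZH2", "kind": "gene_main", "gene": "EZH2", "log_hazard": 0.27, "center": 0.0588, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "U2AF1", "kind": "gene_main", "gene": "U2AF1", "log_hazard": 0.247, "center": 0.0866, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "SRSF2", "kind": "gene_main", "gene": "SRSF2", "log_hazard": 0.239, "center": 0.158, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "DNMT3A", "kind": "gene_main", "gene": "DNMT3A", "log_hazard": 0.221, "center": 0.161, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "ASXL1", "kind": "gene_main", "gene": "ASXL1", "log_hazard": 0.213, "center": 0.252, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "KRAS", "kind": "gene_main", "gene": "KRAS", "log_hazard": 0.202, "center": 0.0271, "best_value": 0.0, "worst_value": 1.0, "transform": "binary"},
    {"name": "NRES2", "kind": "gene_residual_count", "gene": null, "log_hazard": 0.231, "center": 0.388, "best_value": 0.0, "worst_value": 2.0, "transform": "residual_count"}
  ],
  "residual_genes": ["BCOR", "BCORL1", "CEBPA", "ETNK1", "GATA2", "GNB1", "IDH1", "NF1", "PHF6", "PPM1D", "PRPF8", "PTPN11", "SETBP1", "STAG2", "WT1"],
  "residual_prevalence": {
    "BCOR": 0.0435, "BCORL1": 0.0247, "CEBPA": 0.0123, "ETNK1": 0.0075,
    "GATA2": 0.0109, "GNB1": 0.0062, "IDH1": 0.0127, "NF1": 0.0359,
    "PHF6": 0.0248, "PPM1D": 0.0192, "PRPF8": 0.0112, "PTPN11": 0.0153,
    "SETBP1": 0.0252, "STAG2": 0.071, "WT1": 0.0089
  },
  "sf3b1_alpha_exclusion": ["BCOR", "BCORL1", "NRAS", "RUNX1", "SRSF2", "STAG2"]
}
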