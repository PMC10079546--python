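{
  "schema_version": 1,
  "comment": "IPSS-R point assignments. Each rule list is evaluated in order; the first rule whose comparison (value <op> threshold) holds supplies the points, otherwise the fallback applies. Cytogenetic points are indexed by the 0-4 category (very good .. very poor).",
  "cyto_points": [0.0, 1.0, 2.0, 3.0, 4.0],
  "blasts": {"rules": [{"op": "le", "threshold": 2.0, "points": 0.0}, {"op": "lt", "threshold": 5.0, "points": 1.0}, {"op": "le", "threshold": 10.0, "points": 2.0}], "fallback": 3.0},
  "hemoglobin": {"rules": [{"op": "lt", "threshold": 8.0, "points": 1.5}, {"op": "lt", "threshold": 10.0, "points": 1.0}], "fallback": 0.0},
  "platelets": {"rules": [{"op": "lt", "threshold": 50.0, "points": 1.0}, {"op": "lt", "threshold": 100.0, "points": 0.5}], "fallback": 0.0},
  "anc": {"rules": [{"op": "lt", "threshold": 0.8, "points": 0.5}], "fallback": 0.0},
  "category_cutpoints": [1.5, 3.0, 4.5, 6.0],
  "category_labels": ["Very Low", "Low", "Intermediate", "High", "Very High"]
}
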