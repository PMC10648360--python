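{
  "schema_version": 1,
  "model_id": "BETAMIX-M3a",
  "type": "betamix",
  "spec": "M3",
  "components": 1,
  "truncated": false,
  "bounds": [0.315, 1.0],
  "gap": 0.0,
  "provenance": "Published FACT-L to SF-6D beta-mixture coefficients (one component, boundary mass at full health, specification M3: five domain scores). Coefficients stored verbatim as printed. Rescaling bounds fixed at (0.315, 1): evaluating C1_mu at the published mean domain scores gives mu = 0.670 and 0.315 + 0.685*0.670 reproduces the published mean utility 0.774, which pins the rescaling. The PM_ub intercept implies near-zero boundary probability at zero covariates; whether covariates were centred is not stated, so the values are kept verbatim.",
  "feature_names": ["pwb", "swb", "ewb", "fwb", "lcs"],
  "c1_mu": {
    "pwb": 0.10784,
    "swb": -0.00165,
    "ewb": 0.001,
    "fwb": 0.05047,
    "lcs": 0.01068,
    "_cons": -2.88634
  },
  "c1_lnphi": {
    "_cons": 2.549
  },
  "pm_ub": {
    "pwb": 0.61565,
    "swb": 0.09495,
    "ewb": 0.00483,
    "fwb": 0.1481,
    "lcs": 0.19941,
    "_cons": -29.13472
  },
  "c1_phi": 12.79427
}
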