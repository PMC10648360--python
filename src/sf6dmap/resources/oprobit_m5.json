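{
  "schema_version": 1,
  "model_id": "OPROBIT-M5",
  "type": "response_mapping",
  "spec": "M5",
  "sex_coding": "1=male,0=female",
  "provenance": "Published FACT-L to SF-6D response-mapping coefficients (ordered probit, specification M5: five domain scores, their squares, age, sex). Coefficients stored verbatim as printed; the gender regressor is interpreted as 1=male, consistent with the reported positive male/utility association.",
  "feature_names": ["pwb", "swb", "ewb", "fwb", "lcs", "pwb_sq", "swb_sq", "ewb_sq", "fwb_sq", "lcs_sq", "age", "sex"],
  "dimensions": [
    {
      "name": "physical_functioning",
      "n_levels": 6,
      "coefficients": {
        "pwb": -0.10035,
        "swb": -0.08415,
        "ewb": 0.19117,
        "fwb": -0.1034,
        "lcs": 0.39364,
        "pwb_sq": -0.00187,
        "swb_sq": 0.00243,
        "ewb_sq": -0.00433,
        "fwb_sq": 0.0004,
        "lcs_sq": -0.00909,
        "age": 0.00696,
        "sex": -0.33676
      },
      "cutpoints": [-1.0387, 0.15058, 0.84777, 1.75682, 3.01388]
    },
    {
      "name": "role_limitations",
      "n_levels": 4,
      "coefficients": {
        "pwb": 0.04258,
        "swb": -0.11853,
        "ewb": 0.07062,
        "fwb": -0.15476,
        "lcs": 0.07531,
        "pwb_sq": -0.00533,
        "swb_sq": 0.00319,
        "ewb_sq": -0.00082,
        "fwb_sq": 0.00259,
        "lcs_sq": -0.00205,
        "age": 0.00513,
        "sex": -0.07934
      },
      "cutpoints": [-3.31164, -2.27073, -1.16103]
    },
    {
      "name": "social_functioning",
      "n_levels": 5,
      "coefficients": {
        "pwb": 0.02495,
        "swb": -0.06716,
        "ewb": 0.04289,
        "fwb": -0.09566,
        "lcs": 0.04314,
        "pwb_sq": -0.00529,
        "swb_sq": 0.00138,
        "ewb_sq": -0.00072,
        "fwb_sq": 0.00038,
        "lcs_sq": -0.00116,
        "age": 0.00562,
        "sex": -0.08691
      },
      "cutpoints": [-4.07685, -2.837, -2.02446, -1.0889]
    },
    {
      "name": "pain",
      "n_levels": 6,
      "coefficients": {
        "pwb": 0.09956,
        "swb": 0.01935,
        "ewb": 0.03117,
        "fwb": 0.00054,
        "lcs": 0.06599,
        "pwb_sq": -0.00611,
        "swb_sq": -0.00028,
        "ewb_sq": 1e-05,
        "fwb_sq": -0.00117,
        "lcs_sq": -0.00245,
        "age": 0.00101,
        "sex": -0.05482
      },
      "cutpoints": [-1.036, -0.39104, 1.04159, 1.85376, 2.5435]
    },
    {
      "name": "mental_health",
      "n_levels": 5,
      "coefficients": {
        "pwb": 0.14086,
        "swb": -0.07695,
        "ewb": -0.28455,
        "fwb": 0.02716,
        "lcs": -0.01363,
        "pwb_sq": -0.00397,
        "swb_sq": 0.00037,
        "ewb_sq": 0.00308,
        "fwb_sq": -0.00148,
        "lcs_sq": -0.00078,
        "age": -0.00865,
        "sex": 0.01211
      },
      "cutpoints": [-6.57599, -4.49802, -3.12214, -1.84889]
    },
    {
      "name": "vitality",
      "n_levels": 5,
      "coefficients": {
        "pwb": -0.11093,
        "swb": -0.16562,
        "ewb": -0.05456,
        "fwb": -0.07315,
        "lcs": 0.11623,
        "pwb_sq": -0.00112,
        "swb_sq": 0.00411,
        "ewb_sq": -0.00015,
        "fwb_sq": 0.0001,
        "lcs_sq": -0.00508,
        "age": 0.00099,
        "sex": 0.09509
      },
      "cutpoints": [-7.42327, -4.8017, -3.77475, -2.1128]
    }
  ]
}
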