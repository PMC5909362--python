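[
 {
  "combination": "Mo-Mo",
  "alpha": 0.00997, "alpha_sigma": 5e-05,
  "beta": -0.186, "beta_sigma": 0.001,
  "Y0": 0.0938, "Y0_sigma": 0.0008,
  "reference_kvp": 28,
  "mu_en": 0.91, "mu_en_sigma": 0.04,
  "mu_en_by_kvp": {
   "22": [1.04, 0.05], "24": [0.95, 0.04], "26": [0.89, 0.04],
   "28": [0.84, 0.04], "30": [0.81, 0.03]
  },
  "kvp_validity": [22, 34]
 },
 {
  "combination": "Mo-Rh",
  "alpha": 0.00892, "alpha_sigma": 8e-05,
  "beta": -0.18, "beta_sigma": 0.002,
  "Y0": 0.0739, "Y0_sigma": 0.0008,
  "reference_kvp": 28,
  "mu_en": 0.73, "mu_en_sigma": 0.02,
  "mu_en_by_kvp": {
   "24": [0.8, 0.03], "26": [0.75, 0.02], "28": [0.72, 0.02],
   "30": [0.7, 0.02], "32": [0.68, 0.02]
  },
  "kvp_validity": [22, 34]
 },
 {
  "combination": "Rh-Rh",
  "alpha": 0.0078, "alpha_sigma": 0.0002,
  "beta": -0.149, "beta_sigma": 0.006,
  "Y0": 0.0707, "Y0_sigma": 0.0003,
  "reference_kvp": 28,
  "mu_en": 0.68, "mu_en_sigma": 0.04,
  "mu_en_by_kvp": {
   "26": [0.76, 0.04], "28": [0.71, 0.04], "30": [0.67, 0.04],
   "32": [0.64, 0.03], "34": [0.61, 0.03]
  },
  "kvp_validity": [22, 34]
 },
 {
  "combination": "W-Rh",
  "alpha": 0.00271, "alpha_sigma": 4e-05,
  "beta": -0.047, "beta_sigma": 0.001,
  "Y0": 0.031, "Y0_sigma": 0.001,
  "reference_kvp": 28,
  "mu_en": 0.57, "mu_en_sigma": 0.02,
  "mu_en_by_kvp": {
   "26": [0.61, 0.02], "28": [0.59, 0.02], "30": [0.56, 0.02],
   "32": [0.54, 0.02], "34": [0.53, 0.02]
  },
  "kvp_validity": [22, 34]
 },
 {
  "combination": "W-Ag",
  "alpha": 0.00371, "alpha_sigma": 9e-05,
  "beta": -0.066, "beta_sigma": 0.003,
  "Y0": 0.0391, "Y0_sigma": 0.0009,
  "reference_kvp": 28,
  "mu_en": 0.53, "mu_en_sigma": 0.02,
  "mu_en_by_kvp": {
   "26": [0.58, 0.02], "28": [0.55, 0.02], "30": [0.52, 0.03],
   "32": [0.5, 0.02], "34": [0.48, 0.02]
  },
  "kvp_validity": [22, 34]
 }
]
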