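{
 "reference-ge-senographe-ds": {
  "FID_cm": 63.5,
  "yields": {
   "Mo-Mo": {"Y": 0.0938, "sigma": 0.0008},
   "Mo-Rh": {"Y": 0.0739, "sigma": 0.0008},
   "Rh-Rh": {"Y": 0.0707, "sigma": 0.0003}
  }
 },
 "reference-hologic-selenia-dimensions": {
  "FID_cm": 70.0,
  "yields": {
   "W-Rh": {"Y": 0.031, "sigma": 0.001},
   "W-Ag": {"Y": 0.0391, "sigma": 0.0009}
  }
 }
}
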