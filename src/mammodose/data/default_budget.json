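{
 "sigma_d_cm": 0.5,
 "sigma_fid_cm": 0.0,
 "sigma_kvp": 0.0,
 "use_calibration_sigmas": true
}
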