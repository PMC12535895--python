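{
  "model": {
    "tau_roll_s": 5.0,
    "tau_pitch_s": 5.0,
    "tau_yaw_s": 18.0,
    "h_yr_per_s": 0.03870377224005106,
    "h_yp_per_s": 0.0,
    "yaw_gain": 1.0
  },
  "scenario": {
    "intervention": {"kind": "set_yaw_gain", "value": 0.8}
  }
}
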