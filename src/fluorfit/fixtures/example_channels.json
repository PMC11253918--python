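{
  "mu": [
    6000.0
  ],
  "sigma": [
    600.0
  ],
  "bg_sigma": [
    600.0
  ],
  "bg_mu": [
    0.0
  ],
  "variance_mode": "linear"
}
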