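{
  "edman_failure": 0.05,
  "dye_loss": [
    0.03
  ],
  "detach": 0.01,
  "dud": [
    0.0
  ],
  "initial_block": 0.02,
  "cyclic_block": 0.0,
  "fixed": []
}
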