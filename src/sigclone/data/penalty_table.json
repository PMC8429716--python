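{
 "5": {
  "100": 0.5,
  "300": 0.5,
  "1000": 1.0
 }
}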