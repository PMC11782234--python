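{
 "time_scale_ms": 1.4582147275335842,
 "calibrated": true
}
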