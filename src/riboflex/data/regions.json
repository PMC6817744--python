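{
  "P1": [[13, 20], [75, 84]],
  "P2": [[25, 31], [39, 45]],
  "P3": [[54, 59], [67, 72]],
  "L2": [[32, 38]],
  "L3": [[60, 66]],
  "J1/2": [[21, 24]],
  "J2/3": [[46, 53]],
  "J3/1": [[73, 74]]
}
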