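{
  "iron": {"ear": 22, "rdi": 27},
  "calcium": {"ear": 840, "rdi": 1000},
  "folate_dfe": {"ear": 520, "rdi": 600},
  "iodine": {"ear": 160, "rdi": 220},
  "zinc": {"ear": 9, "rdi": 11}
}
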