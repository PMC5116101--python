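{
  "grains": {"min": 8.5},
  "vegetables": {"min": 5},
  "fruit": {"min": 2},
  "meat": {"min": 3.5},
  "dairy": {"min": 2.5},
  "fats_oils": {"lo": 0, "hi": 2.5},
  "discretionary": {"lo": 0, "hi": 2.5}
}
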