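{
  "name": "A100",
  "sm_count": 108,
  "clock_max_ghz": 1.41,
  "clock_sustained_ghz": 1.41,
  "throughput_per_instruction": 64,
  "caps": ["packing2"],
  "note": "Ampere: 16-bit packing only; add/sub share the max issue port"
}
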