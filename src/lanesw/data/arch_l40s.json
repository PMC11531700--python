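{
  "name": "L40S",
  "sm_count": 142,
  "clock_max_ghz": 2.56,
  "clock_sustained_ghz": 2.11,
  "throughput_per_instruction": 64,
  "caps": ["packing2", "dual_port"],
  "note": "Ada: 16-bit packing plus a second FP port for add/sub"
}
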