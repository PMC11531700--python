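{
  "name": "H100",
  "sm_count": 132,
  "clock_max_ghz": 1.98,
  "clock_sustained_ghz": 1.98,
  "throughput_per_instruction": 64,
  "caps": ["packing2", "dual_port", "dpx_fused"],
  "note": "Hopper: packing, dual-port ALU, and fused add+max DP instructions"
}
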