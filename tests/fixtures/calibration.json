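{
  "comment": "End-to-end displacement tolerance calibrated once from a noise-free oracle sweep of the full filter chain (synthetic lean-and-return trials, reach 12-28 cm, seed 1). The chain systematically overestimates by ~15-20% (drift-filter transient plus the bounded limit-cycle jitter of the normalized-gradient correction); the frozen tolerance bounds the observed 20 cm-trial error with margin.",
  "noise_free_reach_sweep_cm": [12.0, 16.0, 20.0, 24.0, 28.0],
  "reach20_abs_tolerance_cm": 4.5
}
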