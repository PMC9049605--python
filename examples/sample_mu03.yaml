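# ACHR sampling of the flux polytope at growth rate 0.3/h: growth fixed,
# substrate uptake confined to [v*, 1.1·v*] around its minimum, 1000
# samples summarised as median ± MAD (also relative to substrate uptake).
name: toy-sampling
mode: sample
model: overflow_toy.json
seed: 7
out_dir: out_sample
sample:
  growth_rate: 0.3
  exchange_id: EX_S
  slack: 0.10
  n_samples: 1000
  thinning: 10
  relative: true
  write_samples: false
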