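# Batch growth with overflow: ethanol accumulates while glucose is in
# excess (pool-limited growth), then is re-assimilated after depletion.
# The pool bound is raised 25% for batch conditions.
name: toy-batch-diauxie
mode: batch
model: overflow_toy.json
seed: 1
out_dir: out_batch
edits:
  - {kind: scale_pool, factor: 1.25}
batch:
  initial:
    V: 1.0          # l
    X: 0.1          # gDW/l
    conc: {s: 50.0} # mmol/l
  kinetics:
    - {exchange_id: EX_S, q_max: 10.0, k_m: 0.28}
    - {exchange_id: EX_etoh, q_max: 2.0, k_m: 0.5}
  dt: 0.05
  t_end: 12.0
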