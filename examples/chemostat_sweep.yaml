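# Glucose-limited chemostat sweep on the overflow toy: fix growth to each
# dilution rate, minimise substrate uptake, convert specific rates into
# reactor concentrations via the steady-state balances.
name: toy-chemostat-sweep
mode: chemostat
model: overflow_toy.json
seed: 1
out_dir: out_chemostat
chemostat:
  feed: {exchange_id: EX_S, concentration: 20.0}   # mmol/l
  d_from: 0.02
  d_to: 0.48
  d_step: 0.02
  ethanol_exchange_id: EX_etoh
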