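# Fed-batch: batch phase, then an exponential glucose feed from 2 h with
# the quasi-steady uptake bound F(t)·c_feed/(X·V); an event caps oxygen
# uptake at 4 h (e.g. mass-transfer limitation) and flags the state.
name: toy-fedbatch-oxygen-event
mode: fedbatch
model: overflow_toy.json
seed: 1
out_dir: out_fedbatch
fedbatch:
  initial:
    V: 0.5
    X: 0.2
    conc: {s: 5.0}
  kinetics:
    - {exchange_id: EX_S, q_max: 10.0, k_m: 0.28}
  feed:
    start_time: 2.0
    rate: 0.02            # l/h at start
    kind: exponential
    k: 0.05               # 1/h
    feed_conc: {s: 500.0} # mmol/l
  events:
    - action: set_exchange_bound
      time: 4.0
      params: {reaction_id: EX_o2_REV, lower: 0.0, upper: 0.5}
      flag: oxygen_limited
  dt: 0.02
  t_end: 8.0
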