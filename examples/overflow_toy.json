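{
 "metabolites": [
  {
   "id": "s",
   "name": "substrate",
   "compartment": "c"
  },
  {
   "id": "etoh",
   "name": "ethanol",
   "compartment": "c"
  },
  {
   "id": "o2",
   "name": "oxygen",
   "compartment": "c"
  },
  {
   "id": "co2",
   "name": "carbon dioxide",
   "compartment": "c"
  },
  {
   "id": "x",
   "name": "biomass precursor",
   "compartment": "c"
  },
  {
   "id": "prot_pool",
   "name": "protein pool",
   "compartment": "c"
  }
 ],
 "reactions": [
  {
   "id": "EX_S",
   "stoich": {
    "s": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "name": "substrate uptake"
  },
  {
   "id": "EX_o2_REV",
   "stoich": {
    "o2": 1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "oxygen uptake"
  },
  {
   "id": "EX_etoh",
   "stoich": {
    "etoh": -1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "ethanol secretion"
  },
  {
   "id": "EX_co2",
   "stoich": {
    "co2": -1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "CO2 secretion"
  },
  {
   "id": "prot_pool_exchange",
   "stoich": {
    "prot_pool": 1.0
   },
   "lb": 0.0,
   "ub": 0.02,
   "name": ""
  },
  {
   "id": "R_resp",
   "stoich": {
    "s": -1.0,
    "o2": -2.0,
    "prot_pool": -0.01,
    "x": 0.1,
    "co2": 2.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "respiratory route"
  },
  {
   "id": "R_ferm",
   "stoich": {
    "s": -1.0,
    "prot_pool": -0.002,
    "x": 0.05,
    "etoh": 1.0,
    "co2": 2.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "fermentative route"
  },
  {
   "id": "R_grow",
   "stoich": {
    "x": -1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "growth"
  },
  {
   "id": "EX_etoh_REV",
   "stoich": {
    "etoh": 1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "ethanol uptake"
  },
  {
   "id": "R_assim",
   "stoich": {
    "etoh": -1.0,
    "o2": -1.0,
    "prot_pool": -0.012,
    "x": 0.025,
    "co2": 1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": "ethanol assimilation"
  }
 ],
 "objective": "R_grow",
 "ec": {
  "pool_exchange_id": "prot_pool_exchange",
  "pool_metabolite_id": "prot_pool",
  "pool_ub": 0.02,
  "pool_coefficients": {
   "R_resp": 0.01,
   "R_ferm": 0.002,
   "R_assim": 0.012
  }
 }
}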