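{
 "metabolites": [
  {
   "id": "a",
   "name": "substrate A",
   "compartment": "c"
  },
  {
   "id": "b",
   "name": "substrate B",
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
   "id": "EX_A",
   "stoich": {
    "a": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "name": ""
  },
  {
   "id": "EX_B",
   "stoich": {
    "b": 1.0
   },
   "lb": 0.0,
   "ub": 10.0,
   "name": ""
  },
  {
   "id": "EX_co2",
   "stoich": {
    "co2": -1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": ""
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
   "id": "R_A",
   "stoich": {
    "a": -1.0,
    "prot_pool": -0.008,
    "x": 0.1,
    "co2": 2.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": ""
  },
  {
   "id": "R_B",
   "stoich": {
    "b": -1.0,
    "prot_pool": -0.01,
    "x": 0.1,
    "co2": 2.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": ""
  },
  {
   "id": "R_grow",
   "stoich": {
    "x": -1.0
   },
   "lb": 0.0,
   "ub": 1000.0,
   "name": ""
  }
 ],
 "objective": "R_grow",
 "ec": {
  "pool_exchange_id": "prot_pool_exchange",
  "pool_metabolite_id": "prot_pool",
  "pool_ub": 0.02,
  "pool_coefficients": {
   "R_A": 0.008,
   "R_B": 0.01
  }
 }
}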