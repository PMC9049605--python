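"""Scenario-driven runs: one YAML file binds a model, strain edits and a
simulation mode into a reproducible run with provenance.

A scenario declares::

    model: {path: toy.json, format: json}   # or  model: toy.json
    edits:                                   # optional strain modifications
      - {kind: scale_pool, factor: 1.25}
    mode: chemostat | batch | fedbatch | sample | protein_cost
    seed: 1
    out_dir: results
    <mode>: {...}                            # mode-specific block

Outputs are CSV files plus a provenance JSON recording the config hash,
model checksum, solver settings, seed and library versions, so a rerun
with the same scenario reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .chemostat import FeedSpec, chemostat_sweep, critical_dilution, \
    sweep_to_records
from .dfba import (Event, FeedProfile, ReactorState, RegulationRule,
                   UptakeKinetics, simulate_dynamic)
from .lp import SOLVER_SETTINGS
from .model import ModelEdit, apply_edit, load_model
from .protein_cost import SubstrateSpec, protein_cost_table
from .sampling import (SamplingSetup, achr_sample, prepare_sampling_model,
                       summarize_samples, validate_samples)

MODES = ("chemostat", "batch", "fedbatch", "sample", "protein_cost")


class ScenarioError(ValueError):
    """Scenario file violates the schema; the message names the key."""


@dataclass
class Scenario:
    mode: str
    model_path: str
    model_format: str | None
    edits: list[ModelEdit]
    seed: int
    out_dir: str
    params: dict
    name: str = ""
    raw: dict = field(default_factory=dict)


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise ScenarioError(f"missing key {key!r} in {context}")
    return block[key]


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScenarioError("scenario file must contain a mapping")
    mode = _require(raw, "mode", "scenario")
    if mode not in MODES:
        raise ScenarioError(f"unknown mode {mode!r}; expected one of {MODES}")
    model = _require(raw, "model", "scenario")
    if isinstance(model, str):
        model_path, model_format = model, None
    else:
        model_path = _require(model, "path", "model block")
        model_format = model.get("format")
    base = os.path.dirname(os.path.abspath(path))
    if not os.path.isabs(model_path):
        model_path = os.path.join(base, model_path)
    edits = []
    for i, e in enumerate(raw.get("edits", []) or []):
        kind = _require(e, "kind", f"edits[{i}]")
        payload = {k: v for k, v in e.items() if k != "kind"}
        edits.append(ModelEdit(kind=kind, payload=payload))
    params = raw.get(mode, {}) or {}
    if not params:
        raise ScenarioError(f"missing mode block {mode!r}")
    out_dir = raw.get("out_dir", "results")
    if not os.path.isabs(out_dir):
        out_dir = os.path.join(base, out_dir)
    return Scenario(mode=mode, model_path=model_path,
                    model_format=model_format, edits=edits,
                    seed=int(raw.get("seed", 0)), out_dir=out_dir,
                    params=params, name=raw.get("name", ""), raw=raw)


def _feed_spec(block: dict) -> FeedSpec:
    return FeedSpec(
        substrate_exchange_id=_require(block, "exchange_id", "feed block"),
        concentration=float(_require(block, "concentration", "feed block")),
        unit=block.get("unit", "mmol/l"),
        species=block.get("species"),
        molar_mass=block.get("molar_mass"))


def _kinetics(block: dict) -> UptakeKinetics:
    return UptakeKinetics(
        exchange_id=_require(block, "exchange_id", "kinetics entry"),
        q_max=float(block.get("q_max", 1000.0)),
        k_m=float(block.get("k_m", 0.28)),
        mode=block.get("mode", "michaelis_menten"))


def _event(block: dict) -> Event:
    return Event(action=_require(block, "action", "event entry"),
                 time=block.get("time"),
                 params=block.get("params", {}),
                 flag=block.get("flag"))


def _rule(block: dict) -> RegulationRule:
    return RegulationRule(
        inhibitor_species=_require(block, "inhibitor", "rule entry"),
        inhibited_exchange_id=_require(block, "inhibits", "rule entry"),
        threshold=float(block.get("threshold", 0.1)))


def _feed_profile(block: dict) -> FeedProfile:
    return FeedProfile(
        start_time=float(_require(block, "start_time", "feed profile")),
        rate=float(_require(block, "rate", "feed profile")),
        feed_conc={k: float(v) for k, v in
                   _require(block, "feed_conc", "feed profile").items()},
        kind=block.get("kind", "constant"),
        k=float(block.get("k", 0.0)),
        stop_time=block.get("stop_time"))


def _provenance(sc: Scenario) -> dict:
    import numpy
    import scipy

    cfg = json.dumps(sc.raw, sort_keys=True, default=str).encode()
    with open(sc.model_path, "rb") as fh:
        model_hash = hashlib.sha256(fh.read()).hexdigest()
    return {
        "scenario_name": sc.name,
        "mode": sc.mode,
        "seed": sc.seed,
        "config_sha256": hashlib.sha256(cfg).hexdigest(),
        "model_sha256": model_hash,
        "solver": dict(SOLVER_SETTINGS),
        "versions": {"ecdyn": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
    }


def run_scenario(path, out_dir: str | None = None) -> dict:
    """Execute a scenario file; returns a dict of written output paths."""
    import pandas as pd

    sc = load_scenario(path)
    if out_dir is not None:
        sc.out_dir = out_dir
    os.makedirs(sc.out_dir, exist_ok=True)
    model = load_model(sc.model_path, sc.model_format)
    for edit in sc.edits:
        model = apply_edit(model, edit)

    outputs: dict[str, str] = {}
    p = sc.params
    if sc.mode == "chemostat":
        feed = _feed_spec(_require(p, "feed", "chemostat block"))
        if "grid" in p:
            grid = [float(x) for x in p["grid"]]
        else:
            d0 = float(_require(p, "d_from", "chemostat block"))
            d1 = float(_require(p, "d_to", "chemostat block"))
            step = float(_require(p, "d_step", "chemostat block"))
            grid, d = [], d0
            while d <= d1 + 1e-12:
                grid.append(round(d, 12))
                d += step
        points = chemostat_sweep(model, grid, feed)
        out = os.path.join(sc.out_dir, "points.csv")
        pd.DataFrame(sweep_to_records(points)).to_csv(out, index=False)
        outputs["points"] = out
        if "ethanol_exchange_id" in p:
            dcrit = critical_dilution(points, p["ethanol_exchange_id"],
                                      float(p.get("onset_threshold", 1e-4)))
            outputs["d_crit"] = dcrit
    elif sc.mode in ("batch", "fedbatch"):
        init_block = _require(p, "initial", f"{sc.mode} block")
        initial = ReactorState(
            t=float(init_block.get("t", 0.0)),
            V=float(_require(init_block, "V", "initial state")),
            X=float(_require(init_block, "X", "initial state")),
            conc={k: float(v)
                  for k, v in init_block.get("conc", {}).items()})
        kinetics = [_kinetics(k) for k in p.get("kinetics", [])]
        events = [_event(e) for e in p.get("events", [])]
        rules = [_rule(r) for r in p.get("rules", [])]
        feed = _feed_profile(p["feed"]) if sc.mode == "fedbatch" else None
        if sc.mode == "fedbatch" and "feed" not in p:
            raise ScenarioError("fedbatch block requires a feed profile")
        traj = simulate_dynamic(
            model, initial, kinetics, events=events, rules=rules, feed=feed,
            dt=float(p.get("dt", 0.01)),
            t_end=float(_require(p, "t_end", f"{sc.mode} block")))
        out = os.path.join(sc.out_dir, "trajectory.csv")
        traj.to_dataframe().to_csv(out, index=False)
        outputs["trajectory"] = out
        outputs["depletion_times"] = dict(traj.depletion_times)
    elif sc.mode == "sample":
        setup = SamplingSetup(
            growth_rate=float(_require(p, "growth_rate", "sample block")),
            glucose_exchange_id=_require(p, "exchange_id", "sample block"),
            slack=float(p.get("slack", 0.10)),
            blocked_reaction_ids=tuple(p.get("blocked", [])),
            seed=sc.seed,
            n_samples=int(p.get("n_samples", 1000)),
            thinning=int(p.get("thinning", 100)))
        prep = prepare_sampling_model(model, setup)
        raw = achr_sample(prep, setup, prepared=True)
        valid = validate_samples(raw, prep)
        summary = summarize_samples(valid, setup.glucose_exchange_id
                                    if p.get("relative", True) else None)
        out = os.path.join(sc.out_dir, "summary.csv")
        summary.table.to_csv(out)
        outputs["summary"] = out
        if p.get("write_samples", False):
            sout = os.path.join(sc.out_dir, "samples.csv")
            pd.DataFrame(valid.fluxes,
                         columns=valid.reaction_ids).to_csv(sout, index=False)
            outputs["samples"] = sout
        outputs["retention"] = valid.provenance.get("retention")
    elif sc.mode == "protein_cost":
        subs = [SubstrateSpec(
                    exchange_id=_require(s, "exchange_id", "substrate entry"),
                    carbon_atoms=int(_require(s, "carbon_atoms",
                                              "substrate entry")),
                    molar_mass=s.get("molar_mass"), name=s.get("name", ""))
                for s in _require(p, "substrates", "protein_cost block")]
        ref_id = _require(p, "reference", "protein_cost block")
        ref = next((s for s in subs if s.exchange_id == ref_id),
                   SubstrateSpec(exchange_id=ref_id, carbon_atoms=6))
        table = protein_cost_table(
            model, subs, ref,
            allow_product_accumulation=bool(
                p.get("allow_product_accumulation", False)))
        out = os.path.join(sc.out_dir, "protein_cost.csv")
        pd.DataFrame([t.__dict__ for t in table]).to_csv(out, index=False)
        outputs["protein_cost"] = out

    prov = _provenance(sc)
    prov["outputs"] = {k: v for k, v in outputs.items()
                       if isinstance(v, str)}
    prov_path = os.path.join(sc.out_dir, "provenance.json")
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
    outputs["provenance"] = prov_path
    return outputs
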