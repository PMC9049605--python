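"""Constraint-based model container, I/O and strain/scenario edits.

The in-memory representation is deliberately minimal: a stoichiometric
network with per-reaction flux bounds, plus an optional enzyme-constraint
overlay (``EcInfo``) describing the GECKO-style protein pool.  Two flux
conventions coexist in published models and are both supported:

* plain GEMs use signed fluxes (uptake = negative exchange flux);
* enzyme-constrained models are fully irreversible, with reversible
  reactions split into a forward copy and a ``_REV`` twin, so uptake is a
  positive flux through the ``_REV`` exchange.

:func:`resolve_uptake` hides this difference from downstream modules.

Units: fluxes in mmol·gDW⁻¹·h⁻¹ (biomass reaction: h⁻¹; protein-pool
exchange: g·gDW⁻¹·h⁻¹); pool coefficients in g·h·mmol⁻¹.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

#: Cap used for flux directions the source file leaves unbounded
#: (COBRA community convention), mmol·gDW⁻¹·h⁻¹.
DEFAULT_FLUX_CAP = 1000.0


class ValidationError(ValueError):
    """Model content violates a structural invariant."""


class FormatError(ValueError):
    """A model file could not be parsed in the requested format."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoich`` maps metabolite id to its (signed) coefficient; negative
    coefficients are consumed, positive produced.
    """

    id: str
    stoich: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_FLUX_CAP
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions touching exactly one metabolite."""
        return len(self.stoich) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoich=dict(self.stoich))


@dataclass
class EcInfo:
    """Enzyme-constraint overlay of a GECKO-style model.

    ``pool_coefficient[r]`` is the net protein-pool mass (g·h·mmol⁻¹) drawn
    per unit flux through reaction ``r`` — aggregated over the enzyme draw
    chain when the model uses per-enzyme pseudo-metabolites.
    """

    pool_exchange_id: str
    pool_metabolite_id: str
    pool_upper_bound: float
    enzyme_metabolite_ids: set[str] = field(default_factory=set)
    pool_coefficient: dict[str, float] = field(default_factory=dict)
    #: how the pool draw is encoded: "direct" (reactions consume the pool
    #: metabolite) or "draw_chain" (per-enzyme pseudo-metabolites)
    mode: str = "direct"

    def __post_init__(self) -> None:
        if self.pool_upper_bound <= 0:
            raise ValidationError("protein pool upper bound must be > 0")
        for rid, c in self.pool_coefficient.items():
            if c < 0:
                raise ValidationError(
                    f"negative pool coefficient for reaction {rid!r}")


class MetabolicModel:
    """Stoichiometric network + bounds; the LP substrate for all simulations."""

    def __init__(self, metabolites=(), reactions=(),
                 objective_reaction_id: str | None = None,
                 ec: EcInfo | None = None, name: str = ""):
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction_id = objective_reaction_id
        self.ec = ec
        self.name = name
        for m in metabolites:
            self._add_metabolite(m)
        for r in reactions:
            self._add_reaction(r)

    # -- construction -----------------------------------------------------
    def _add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def _add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoich:
            raise ValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        for mid in rxn.stoich:
            if mid not in self.metabolites:
                raise ValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {mid!r}")
        self.reactions[rxn.id] = rxn

    # -- basic queries ----------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(name=self.name)
        m.metabolites = dict(self.metabolites)
        m.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        m.objective_reaction_id = self.objective_reaction_id
        if self.ec is not None:
            m.ec = EcInfo(
                pool_exchange_id=self.ec.pool_exchange_id,
                pool_metabolite_id=self.ec.pool_metabolite_id,
                pool_upper_bound=self.ec.pool_upper_bound,
                enzyme_metabolite_ids=set(self.ec.enzyme_metabolite_ids),
                pool_coefficient=dict(self.ec.pool_coefficient),
                mode=self.ec.mode,
            )
        return m

    def validate(self) -> None:
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise ValidationError(
                    f"reaction {r.id!r}: lb > ub")
            for mid in r.stoich:
                if mid not in self.metabolites:
                    raise ValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}")


# ---------------------------------------------------------------------------
# Uptake/secretion accessors (convention-blind substrate handling)
# ---------------------------------------------------------------------------

def resolve_uptake(model: MetabolicModel, exchange_id: str) -> tuple[str, int]:
    """Map an exchange id to ``(reaction_id, sign)`` such that
    ``sign * flux`` is the (positive) uptake rate of the exchanged species.

    Handles both the signed plain-GEM convention and the irreversible
    ``_REV``-split convention of enzyme-constrained models.
    """
    rev_id = exchange_id + "_REV"
    if rev_id in model.reactions:
        rxn = model.reactions[rev_id]
        if not rxn.is_exchange:
            raise ValidationError(f"{rev_id!r} is not an exchange reaction")
        coef = next(iter(rxn.stoich.values()))
        if coef > 0:  # ∅ -> m, forward flux imports
            return rev_id, 1
    if exchange_id not in model.reactions:
        raise KeyError(f"unknown exchange reaction {exchange_id!r}")
    rxn = model.reactions[exchange_id]
    if not rxn.is_exchange:
        raise ValidationError(f"{exchange_id!r} is not an exchange reaction")
    coef = next(iter(rxn.stoich.values()))
    # coef > 0: forward flux imports the species; coef < 0: reverse does
    return (exchange_id, 1) if coef > 0 else (exchange_id, -1)


def exchanged_species(rxn: Reaction) -> str:
    if not rxn.is_exchange:
        raise ValidationError(f"{rxn.id!r} is not an exchange reaction")
    return next(iter(rxn.stoich))


def species_exchange_map(model: MetabolicModel) -> dict[str, list[str]]:
    """Map each boundary metabolite id to its exchange reaction ids,
    excluding the protein-pool pseudo-exchange and enzyme metabolites."""
    skip = set()
    if model.ec is not None:
        skip.add(model.ec.pool_metabolite_id)
        skip |= model.ec.enzyme_metabolite_ids
    out: dict[str, list[str]] = {}
    for r in model.exchanges():
        mid = exchanged_species(r)
        if mid in skip:
            continue
        out.setdefault(mid, []).append(r.id)
    return out


def close_uptake_direction(rxn: Reaction, species: str) -> None:
    """Forbid import of ``species`` through exchange ``rxn`` in place."""
    coef = rxn.stoich[species]
    if coef > 0:  # forward flux imports
        rxn.upper_bound = min(rxn.upper_bound, 0.0)
        rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    else:  # reverse flux imports
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)


def close_secretion_direction(rxn: Reaction, species: str) -> None:
    """Forbid export of ``species`` through exchange ``rxn`` in place."""
    coef = rxn.stoich[species]
    if coef < 0:  # forward flux secretes
        rxn.upper_bound = min(rxn.upper_bound, 0.0)
        rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    else:
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)


def medium_rate(model: MetabolicModel, fluxes: dict[str, float],
                species_id: str) -> float:
    """Net specific rate (mmol·gDW⁻¹·h⁻¹) at which ``species_id`` is
    released into the medium; negative values mean consumption."""
    rate = 0.0
    for r in model.exchanges():
        if exchanged_species(r) == species_id:
            rate -= r.stoich[species_id] * fluxes.get(r.id, 0.0)
    return rate


# ---------------------------------------------------------------------------
# Enzyme-constraint detection
# ---------------------------------------------------------------------------

_POOL_PATTERN = re.compile(r"pool", re.IGNORECASE)


def detect_ec_structure(model: MetabolicModel,
                        pool_id_hint: str | None = None) -> EcInfo | None:
    """Detect the GECKO enzyme-constraint structure of a model.

    Returns ``None`` for a plain GEM.  Both encodings are recognised:
    reactions drawing the pool metabolite directly, and draw chains where a
    per-enzyme pseudo-metabolite is produced from the pool (coefficient =
    molecular weight) and consumed by catalysed reactions (coefficient =
    1/k_cat); in the latter case ``pool_coefficient`` aggregates the net
    pool mass per unit flux.
    """
    produced_by: dict[str, list[str]] = {}
    consumed_by: dict[str, list[str]] = {}
    for r in model.reactions.values():
        for mid, c in r.stoich.items():
            (produced_by if c > 0 else consumed_by).setdefault(mid, []).append(r.id)

    candidates = []
    for r in model.exchanges():
        mid = exchanged_species(r)
        coef = r.stoich[mid]
        if coef <= 0 or r.upper_bound <= 0 or not math.isfinite(r.upper_bound):
            continue
        if pool_id_hint is not None:
            if r.id == pool_id_hint or mid == pool_id_hint:
                candidates.append(r)
            continue
        if _POOL_PATTERN.search(r.id) or _POOL_PATTERN.search(mid):
            candidates.append(r)
    if not candidates:
        return None
    if len(candidates) > 1:
        raise ValidationError(
            "ambiguous protein-pool candidates: "
            + ", ".join(r.id for r in candidates)
            + "; pass pool_id_hint")

    pool_rxn = candidates[0]
    pool_met = exchanged_species(pool_rxn)

    enzyme_mets: set[str] = set()
    pool_coeff: dict[str, float] = {}
    draw_rxns: set[str] = set()
    mode_flags = set()

    for rid in consumed_by.get(pool_met, ()):
        r = model.reactions[rid]
        if r.is_exchange:
            continue
        other_products = {m: c for m, c in r.stoich.items()
                          if m != pool_met and c > 0}
        other_consumed = {m: c for m, c in r.stoich.items()
                          if m != pool_met and c < 0}
        if (len(other_products) == 1 and not other_consumed
                and consumed_by.get(next(iter(other_products)))):
            # draw reaction: pool -> enzyme pseudo-metabolite
            enz = next(iter(other_products))
            mw = -r.stoich[pool_met] / r.stoich[enz]
            enzyme_mets.add(enz)
            draw_rxns.add(rid)
            for qid in consumed_by[enz]:
                if qid == rid:
                    continue
                q = model.reactions[qid]
                pool_coeff[qid] = pool_coeff.get(qid, 0.0) - q.stoich[enz] * mw
            mode_flags.add("draw_chain")
        else:
            pool_coeff[rid] = pool_coeff.get(rid, 0.0) - r.stoich[pool_met]
            mode_flags.add("direct")

    mode = mode_flags.pop() if len(mode_flags) == 1 else (
        "mixed" if mode_flags else "direct")
    return EcInfo(
        pool_exchange_id=pool_rxn.id,
        pool_metabolite_id=pool_met,
        pool_upper_bound=pool_rxn.upper_bound,
        enzyme_metabolite_ids=enzyme_mets,
        pool_coefficient=pool_coeff,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Model edits
# ---------------------------------------------------------------------------

def set_flux_bounds(model: MetabolicModel, reaction_id: str,
                    lower: float, upper: float) -> MetabolicModel:
    """Return a copy of ``model`` with the named reaction's bounds replaced."""
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    if lower > upper:
        raise ValidationError(
            f"lower bound {lower} exceeds upper bound {upper}")
    out = model.copy()
    rxn = out.reactions[reaction_id]
    rxn.lower_bound = lower
    rxn.upper_bound = upper
    if out.ec is not None and reaction_id == out.ec.pool_exchange_id:
        out.ec.pool_upper_bound = upper
    return out


_KO_SUFFIX = re.compile(r"^(_REV)?(No\d+)?$")


def _matches_knockout(target: str, reaction_id: str) -> bool:
    if not reaction_id.startswith(target):
        return False
    return _KO_SUFFIX.match(reaction_id[len(target):]) is not None


def apply_knockout(model: MetabolicModel,
                   reaction_ids: list[str]) -> MetabolicModel:
    """Zero the bounds of the listed reactions.

    In irreversible (ec) models a target also matches its ``_REV`` twin and
    GECKO isozyme copies (``<id>No1``, ``<id>_REVNo2``, ...), so a knockout
    removes the whole activity, not one arm of it.
    """
    out = model.copy()
    for target in reaction_ids:
        hits = [rid for rid in out.reactions
                if _matches_knockout(target, rid)]
        if not hits:
            raise KeyError(f"unknown reaction {target!r}")
        for rid in hits:
            out.reactions[rid].lower_bound = 0.0
            out.reactions[rid].upper_bound = 0.0
    return out


def add_reaction(model: MetabolicModel, reaction: Reaction,
                 pool_coefficient: float | None = None,
                 new_metabolites: tuple[Metabolite, ...] = ()) -> MetabolicModel:
    """Append a (possibly heterologous) reaction, optionally wiring its
    protein-pool draw.  New metabolites may be declared alongside."""
    if reaction.id in model.reactions:
        raise ValidationError(f"reaction id {reaction.id!r} already in model")
    if pool_coefficient is not None:
        if pool_coefficient < 0:
            raise ValidationError("pool coefficient must be >= 0")
        if model.ec is None:
            raise ValidationError(
                "cannot assign a pool coefficient on a model without "
                "enzyme constraints")
    out = model.copy()
    for met in new_metabolites:
        if met.id not in out.metabolites:
            out._add_metabolite(met)
    rxn = reaction.copy()
    if pool_coefficient:
        pm = out.ec.pool_metabolite_id
        rxn.stoich[pm] = rxn.stoich.get(pm, 0.0) - pool_coefficient
        out.ec.pool_coefficient[rxn.id] = pool_coefficient
    out._add_reaction(rxn)
    return out


def scale_protein_pool(model: MetabolicModel, factor: float) -> MetabolicModel:
    """Multiply the protein-pool upper bound by ``factor`` (e.g. 1.25 for
    the batch-growth setting); nothing else changes."""
    if model.ec is None:
        raise ValidationError("model has no enzyme constraints")
    if factor <= 0:
        raise ValidationError("pool scale factor must be > 0")
    new_ub = model.ec.pool_upper_bound * factor
    return set_flux_bounds(model, model.ec.pool_exchange_id,
                           model.reactions[model.ec.pool_exchange_id].lower_bound,
                           new_ub)


#: species whose exchanges stay open when secretions are restricted
DEFAULT_SECRETION_KEEP = ("o2", "co2", "h2o", "h")


def _base_species(mid: str) -> str:
    # strip common compartment suffixes: glc__D_e, o2[e], s_1234
    m = re.match(r"^(.*?)(\[[a-z]\]|_[a-z])?$", mid)
    return m.group(1) if m else mid


def restrict_secretions(model: MetabolicModel, allowed_exchange_ids: list[str],
                        keep_species=DEFAULT_SECRETION_KEEP) -> MetabolicModel:
    """Close the secretion direction of every exchange not in the allowed
    list (gases/water/protons configurable via ``keep_species``); uptake
    directions are untouched."""
    allowed = set(allowed_exchange_ids)
    for rid in allowed:
        if rid not in model.reactions:
            raise KeyError(f"unknown exchange reaction {rid!r}")
        if not model.reactions[rid].is_exchange:
            raise ValidationError(f"{rid!r} is not an exchange reaction")
    keep = {s.lower() for s in keep_species}
    out = model.copy()
    pool_ex = model.ec.pool_exchange_id if model.ec else None
    for r in out.reactions.values():
        if not r.is_exchange or r.id in allowed or r.id == pool_ex \
                or r.id == out.objective_reaction_id:
            continue
        mid = exchanged_species(r)
        if _base_species(mid).lower() in keep or mid.lower() in keep:
            continue
        coef = r.stoich[mid]
        if coef < 0:
            # m -> ∅ : forward flux secretes
            r.upper_bound = min(r.upper_bound, 0.0)
            r.lower_bound = min(r.lower_bound, r.upper_bound)
        else:
            # ∅ -> m : reverse flux secretes
            r.lower_bound = max(r.lower_bound, 0.0)
            r.upper_bound = max(r.upper_bound, r.lower_bound)
    return out


def rescale_pool_coefficients(model: MetabolicModel,
                              factors: dict[str, float]) -> MetabolicModel:
    """Multiply selected reactions' pool draw by explicit factors.

    Generic hook for k_cat recalibration: a factor f on reaction r scales
    its pool coefficient by f (equivalently divides the effective k_cat).
    Only applicable to models encoding the pool draw directly.
    """
    if model.ec is None:
        raise ValidationError("model has no enzyme constraints")
    if model.ec.mode != "direct":
        raise ValidationError(
            "pool-coefficient rescaling requires the direct pool encoding")
    out = model.copy()
    pm = out.ec.pool_metabolite_id
    for rid, f in factors.items():
        if rid not in out.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
        if f <= 0:
            raise ValidationError(f"rescale factor for {rid!r} must be > 0")
        r = out.reactions[rid]
        if pm not in r.stoich:
            raise ValidationError(f"reaction {rid!r} draws no pool")
        r.stoich[pm] *= f
        out.ec.pool_coefficient[rid] = -r.stoich[pm]
    return out


def rescale_small_coefficients(model: MetabolicModel, tolerance: float,
                               coefficient_cap: float = 1e9,
                               ) -> tuple[MetabolicModel, dict[str, float]]:
    """Rescale enzyme/pool mass units so no nonzero |coefficient| falls
    below ``tolerance`` (a numerical-stability guard for the solver).

    For a metabolite with a dedicated exchange the unit change scales that
    exchange's flux (and bounds) by a power of ten, recorded in the returned
    report; otherwise the metabolite's whole balance row is scaled, which
    leaves every flux unchanged.  Solution sets are preserved up to the
    reported flux scale factors.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    out = model.copy()
    report: dict[str, float] = {}
    by_met: dict[str, list[Reaction]] = {}
    for r in out.reactions.values():
        for mid in r.stoich:
            by_met.setdefault(mid, []).append(r)

    for mid, rxns in by_met.items():
        nonzero = [abs(r.stoich[mid]) for r in rxns if r.stoich[mid] != 0]
        if not nonzero or min(nonzero) >= tolerance:
            continue
        s = 10.0 ** math.ceil(math.log10(tolerance / min(nonzero)))
        exchanges = [r for r in rxns if r.is_exchange]
        if exchanges:
            # unit change: scale non-exchange coefficients and exchange bounds
            worst = max(abs(r.stoich[mid]) for r in rxns if not r.is_exchange)
            if worst * s > coefficient_cap:
                raise ValidationError(
                    f"cannot rescale metabolite {mid!r}: coefficient "
                    f"{worst} would exceed cap {coefficient_cap} at scale {s}")
            for r in rxns:
                if r.is_exchange:
                    r.lower_bound *= s
                    r.upper_bound *= s
                    report[r.id] = s
                else:
                    r.stoich[mid] *= s
            if out.ec is not None and mid == out.ec.pool_metabolite_id:
                out.ec.pool_upper_bound *= s
                out.ec.pool_coefficient = {
                    k: v * s for k, v in out.ec.pool_coefficient.items()}
        else:
            worst = max(nonzero)
            if worst * s > coefficient_cap:
                raise ValidationError(
                    f"cannot rescale metabolite {mid!r}: coefficient "
                    f"{worst} would exceed cap {coefficient_cap} at scale {s}")
            for r in rxns:
                r.stoich[mid] *= s
    return out, report


# ---------------------------------------------------------------------------
# Declarative edits (scenario files)
# ---------------------------------------------------------------------------

EDIT_KINDS = ("set_bounds", "knockout", "add_reaction", "scale_pool",
              "restrict_secretion", "rescale_kcat")


@dataclass
class ModelEdit:
    """A declarative strain/scenario modification, validated per kind."""

    kind: str
    payload: dict

    _REQUIRED = {
        "set_bounds": {"reaction_id", "lower", "upper"},
        "knockout": {"reaction_ids"},
        "add_reaction": {"id", "stoich"},
        "scale_pool": {"factor"},
        "restrict_secretion": {"allowed_exchange_ids"},
        "rescale_kcat": {"factors"},
    }

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        missing = self._REQUIRED[self.kind] - set(self.payload)
        if missing:
            raise ValidationError(
                f"edit {self.kind!r} missing payload keys {sorted(missing)}")


def apply_edit(model: MetabolicModel, edit: ModelEdit) -> MetabolicModel:
    p = edit.payload
    if edit.kind == "set_bounds":
        return set_flux_bounds(model, p["reaction_id"], p["lower"], p["upper"])
    if edit.kind == "knockout":
        return apply_knockout(model, list(p["reaction_ids"]))
    if edit.kind == "add_reaction":
        mets = tuple(Metabolite(**m) if isinstance(m, dict) else m
                     for m in p.get("new_metabolites", ()))
        rxn = Reaction(id=p["id"], stoich=dict(p["stoich"]),
                       lower_bound=p.get("lower", 0.0),
                       upper_bound=p.get("upper", DEFAULT_FLUX_CAP))
        return add_reaction(model, rxn,
                            pool_coefficient=p.get("pool_coefficient"),
                            new_metabolites=mets)
    if edit.kind == "scale_pool":
        return scale_protein_pool(model, p["factor"])
    if edit.kind == "restrict_secretion":
        keep = p.get("keep_species", DEFAULT_SECRETION_KEEP)
        return restrict_secretions(model, list(p["allowed_exchange_ids"]), keep)
    if edit.kind == "rescale_kcat":
        return rescale_pool_coefficients(model, dict(p["factors"]))
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# I/O: JSON dialect and SBML (Level 3 + FBC)
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    d: dict = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "stoich": dict(r.stoich),
             "lb": r.lower_bound, "ub": r.upper_bound, "name": r.name}
            for r in model.reactions.values()
        ],
    }
    if model.objective_reaction_id:
        d["objective"] = model.objective_reaction_id
    if model.ec is not None:
        d["ec"] = {
            "pool_exchange_id": model.ec.pool_exchange_id,
            "pool_metabolite_id": model.ec.pool_metabolite_id,
            "pool_ub": model.ec.pool_upper_bound,
            "pool_coefficients": dict(model.ec.pool_coefficient),
        }
    return d


def _model_from_dict(d: dict) -> MetabolicModel:
    try:
        mets = [Metabolite(id=m["id"], name=m.get("name", ""),
                           compartment=m.get("compartment", "c"))
                for m in d["metabolites"]]
        rxns = []
        for r in d["reactions"]:
            lb = r.get("lb")
            ub = r.get("ub")
            rxns.append(Reaction(
                id=r["id"], stoich={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=-DEFAULT_FLUX_CAP if lb is None else float(lb),
                upper_bound=DEFAULT_FLUX_CAP if ub is None else float(ub),
                name=r.get("name", "")))
    except KeyError as e:
        raise FormatError(f"missing required key {e.args[0]!r}") from None
    model = MetabolicModel(mets, rxns, objective_reaction_id=d.get("objective"))
    ec = d.get("ec")
    if ec:
        pool_ex = ec["pool_exchange_id"]
        if pool_ex not in model.reactions:
            raise FormatError(
                f"ec block references unknown pool exchange {pool_ex!r}")
        pm = ec.get("pool_metabolite_id") or exchanged_species(
            model.reactions[pool_ex])
        model.ec = EcInfo(
            pool_exchange_id=pool_ex,
            pool_metabolite_id=pm,
            pool_upper_bound=float(ec.get("pool_ub",
                                          model.reactions[pool_ex].upper_bound)),
            pool_coefficient={k: float(v)
                              for k, v in ec.get("pool_coefficients", {}).items()},
        )
    return model


def save_model(model: MetabolicModel, path, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
    elif format == "sbml":
        _write_sbml(model, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a model from the JSON dialect or SBML L3 (+FBC flux bounds).

    Unbounded directions are capped at ±:data:`DEFAULT_FLUX_CAP`.
    """
    spath = str(path)
    if format is None:
        format = "sbml" if spath.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        try:
            with open(spath) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"invalid JSON in {spath}: {e}") from None
        return _model_from_dict(d)
    if format == "sbml":
        return _read_sbml(spath)
    raise ValueError(f"unknown model format {format!r}")


def _cap(value: float, default: float) -> float:
    if value is None or not math.isfinite(value):
        return default
    return max(-DEFAULT_FLUX_CAP, min(DEFAULT_FLUX_CAP, value)) \
        if abs(value) > DEFAULT_FLUX_CAP else value


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.name or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = {m.compartment for m in model.metabolites.values()}
    for cid in sorted(compartments):
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)
    for met in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(met.id)
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    bounds: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds:
            pid = f"fb_{len(bounds)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds[value] = pid
        return bounds[value]

    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coef in rxn.stoich.items():
            sr = r.createReactant() if coef < 0 else r.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    if model.objective_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse error in {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"no <model> element in {path}")

    mets = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mets.append(Metabolite(id=sp.getId(), name=sp.getName() or "",
                               compartment=sp.getCompartment() or "c"))

    params = {}
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        params[p.getId()] = p.getValue()

    rxns = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb, ub = -DEFAULT_FLUX_CAP, DEFAULT_FLUX_CAP
        if rplug is not None:
            lb_id = rplug.getLowerFluxBound()
            ub_id = rplug.getUpperFluxBound()
            if lb_id:
                lb = params.get(lb_id, lb)
            if ub_id:
                ub = params.get(ub_id, ub)
        elif not sr.getReversible():
            lb = 0.0
        rxns.append(Reaction(id=sr.getId(), stoich=stoich,
                             lower_bound=_cap(lb, -DEFAULT_FLUX_CAP),
                             upper_bound=_cap(ub, DEFAULT_FLUX_CAP),
                             name=sr.getName() or ""))

    objective = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()

    model = MetabolicModel(mets, rxns, objective_reaction_id=objective,
                           name=sm.getId() or "")
    try:
        model.ec = detect_ec_structure(model)
    except ValidationError:
        model.ec = None
    return model
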