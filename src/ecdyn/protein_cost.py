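"""Relative protein cost of substrate consumption and biomass yield per C-mol.

The protein cost of a substrate is the flux through the protein-pool
exchange required to consume 1 mmol·gDW⁻¹·h⁻¹ of that substrate as sole
carbon source; the relative cost divides by the same flux for glucose.
"Required" is evaluated as the minimal pool flux consistent with optimal
growth at the fixed unit uptake (lexicographic max-growth-then-min-pool) —
this pins a unique, reproducible value where plain FBA optima are
degenerate, and is the main interpretive choice behind the statistic.

For oligosaccharides whose hydrolysis products could either be metabolised
or escape to the medium, ``allow_product_accumulation`` chooses the basis:
by default the secretion of the other carbon substrates is closed, so the
whole mmol must be consumed; with accumulation allowed, only their uptake
is closed and hydrolysis products may accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lp import lexicographic_solve
from .model import (MetabolicModel, close_secretion_direction,
                    close_uptake_direction, exchanged_species,
                    resolve_uptake)

#: non-carbon species whose uptake stays open during sole-carbon evaluation
NON_CARBON_SPECIES = ("o2", "h2o", "h", "nh4", "pi", "so4")


@dataclass
class SubstrateSpec:
    """A carbon substrate: its exchange, carbon count and molar mass."""

    exchange_id: str
    carbon_atoms: int
    molar_mass: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.carbon_atoms < 1:
            raise ValueError("carbon_atoms must be >= 1")


@dataclass
class ProteinCostResult:
    substrate: str
    pool_flux_at_unit_uptake: float   # g·gDW⁻¹·h⁻¹
    mu_at_unit_uptake: float          # h⁻¹
    relative_cost: float | None
    yield_per_cmol: float | None      # gDW·C-mol⁻¹


def _sole_carbon_model(model: MetabolicModel, exchange_id: str,
                       uptake_rate: float,
                       allow_product_accumulation: bool,
                       keep_species=NON_CARBON_SPECIES) -> MetabolicModel:
    rid, sign = resolve_uptake(model, exchange_id)
    m = model.copy()
    target_species = exchanged_species(m.reactions[rid])
    keep = {s.lower() for s in keep_species}
    pool_ex = m.ec.pool_exchange_id if m.ec else None
    skip_species = {target_species}
    if m.ec is not None:
        skip_species.add(m.ec.pool_metabolite_id)
        skip_species |= m.ec.enzyme_metabolite_ids
    for rxn in m.exchanges():
        if rxn.id == pool_ex:
            continue
        sp = exchanged_species(rxn)
        if sp in skip_species or sp.lower() in keep \
                or sp.lower().startswith("co2"):
            continue
        # biomass sink of toy fixtures: leave open
        if rxn.id == m.objective_reaction_id:
            continue
        close_uptake_direction(rxn, sp)
        if not allow_product_accumulation:
            close_secretion_direction(rxn, sp)
    rxn = m.reactions[rid]
    if sign > 0:
        rxn.lower_bound = uptake_rate
        rxn.upper_bound = uptake_rate
    else:
        rxn.lower_bound = -uptake_rate
        rxn.upper_bound = -uptake_rate
    return m


def pool_cost(model: MetabolicModel, substrate: SubstrateSpec | str,
              uptake_rate: float = 1.0,
              allow_product_accumulation: bool = False,
              growth_reaction_id: str | None = None,
              ) -> tuple[float, float]:
    """Minimal pool flux (g·gDW⁻¹·h⁻¹) consistent with optimal growth at a
    fixed substrate uptake of ``uptake_rate`` mmol·gDW⁻¹·h⁻¹ as sole carbon
    source, and that optimal growth rate.  Returns ``(pool_flux, mu)``."""
    if model.ec is None:
        raise ValueError("protein cost requires an enzyme-constrained model")
    exchange_id = substrate.exchange_id if isinstance(
        substrate, SubstrateSpec) else substrate
    growth = growth_reaction_id or model.objective_reaction_id
    if growth is None:
        raise ValueError("no growth reaction specified")
    if uptake_rate == 0:
        return 0.0, 0.0
    m = _sole_carbon_model(model, exchange_id, uptake_rate,
                           allow_product_accumulation)
    sol = lexicographic_solve(m, [(growth, "max"),
                                  (m.ec.pool_exchange_id, "min")])
    if not sol.ok:
        raise RuntimeError(
            f"substrate {exchange_id!r} cannot support metabolism at uptake "
            f"{uptake_rate} (LP {sol.status} at stage {sol.failed_stage})")
    return sol.fluxes[m.ec.pool_exchange_id], sol.fluxes[growth]


def relative_protein_cost(model: MetabolicModel,
                          substrate: SubstrateSpec | str,
                          reference: SubstrateSpec | str,
                          **kwargs) -> float:
    """Pool flux to consume 1 mmol of ``substrate`` divided by the pool
    flux to consume 1 mmol of ``reference`` (glucose = 1 by definition)."""
    cost_s, _ = pool_cost(model, substrate, **kwargs)
    cost_r, _ = pool_cost(model, reference, **kwargs)
    if cost_r == 0:
        raise ZeroDivisionError("reference substrate has zero pool cost")
    return cost_s / cost_r


def yield_per_cmol(model: MetabolicModel, substrate: SubstrateSpec,
                   uptake_rate: float = 1.0, **kwargs) -> float:
    """Biomass yield in gDW per C-mol of substrate consumed, evaluated at
    the unit-uptake optimum: mu / (uptake_rate·carbon_atoms/1000)."""
    if uptake_rate == 0:
        raise ZeroDivisionError("yield undefined at zero uptake")
    _, mu = pool_cost(model, substrate, uptake_rate, **kwargs)
    return mu / (uptake_rate * substrate.carbon_atoms / 1000.0)


def protein_cost_table(model: MetabolicModel,
                       substrates: list[SubstrateSpec],
                       reference: SubstrateSpec,
                       uptake_rate: float = 1.0,
                       allow_product_accumulation: bool = False,
                       ) -> list[ProteinCostResult]:
    """Relative protein cost and biomass yield per C-mol for each
    substrate, with ``reference`` defining cost 1."""
    ref_cost, _ = pool_cost(model, reference, uptake_rate,
                            allow_product_accumulation)
    out = []
    for sub in substrates:
        cost, mu = pool_cost(model, sub, uptake_rate,
                             allow_product_accumulation)
        out.append(ProteinCostResult(
            substrate=sub.name or sub.exchange_id,
            pool_flux_at_unit_uptake=cost,
            mu_at_unit_uptake=mu,
            relative_cost=cost / ref_cost if ref_cost else None,
            yield_per_cmol=mu / (uptake_rate * sub.carbon_atoms / 1000.0),
        ))
    return out
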