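"""Steady-state chemostat prediction across dilution rates.

At steady state the specific growth rate equals the dilution rate D, so the
biomass reaction is fixed to D and the substrate uptake is minimised
(lexicographic FBA).  Specific rates are converted into reactor
concentrations through the steady-state mass balances of a glucose-limited
chemostat (residual substrate ≈ 0):

    q_s · c_x = D · (c_feed − c_s)        with  c_s = 0
    c_p = q_p · c_x / D                    for every secreted product

The critical dilution rate is the onset of overflow metabolism: the
smallest D at which the fermentative byproduct (ethanol) is secreted above
a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import units
from .lp import lexicographic_solve
from .model import (MetabolicModel, close_uptake_direction,
                    exchanged_species, medium_rate, resolve_uptake,
                    set_flux_bounds)

#: species whose uptake stays open in a minimal chemostat medium
MEDIUM_KEEP_SPECIES = ("o2", "h2o", "h", "nh4", "pi", "so4")

#: ethanol secretion rate marking overflow onset; far above solver noise,
#: far below physiological rates (mmol·gDW⁻¹·h⁻¹)
ETHANOL_ONSET_THRESHOLD = 1e-4

#: byproduct rates below this are solver noise and are not reported
BYPRODUCT_THRESHOLD = 1e-6


class WashoutError(RuntimeError):
    """The dilution rate exceeds the maximum feasible growth rate."""


@dataclass
class FeedSpec:
    """Feed medium for a single-substrate chemostat.

    ``concentration`` is in mmol·l⁻¹ unless ``unit='g/l'``, in which case it
    is converted through the molar-mass registry (``species`` or
    ``molar_mass`` must then be given).
    """

    substrate_exchange_id: str
    concentration: float
    unit: str = "mmol/l"
    species: str | None = None
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("feed concentration must be > 0")
        if self.unit not in ("mmol/l", "g/l"):
            raise ValueError(f"unknown feed unit {self.unit!r}")

    @property
    def mmol_per_l(self) -> float:
        if self.unit == "mmol/l":
            return self.concentration
        mw = self.molar_mass or units.molar_mass(self.species)
        return self.concentration * 1000.0 / mw


@dataclass
class ChemostatPoint:
    """Steady-state solution at one dilution rate."""

    D: float                      # h⁻¹
    q_s: float                    # mmol·gDW⁻¹·h⁻¹
    c_x: float                    # gDW·l⁻¹
    c_s: float                    # residual substrate, mmol·l⁻¹ (≈ 0)
    yield_gdw_per_mmol: float     # D / q_s
    Y_xs: float | None            # g·g⁻¹ when the substrate MW is known
    OUR: float                    # specific O2 uptake, mmol·gDW⁻¹·h⁻¹
    CPR: float                    # specific CO2 production, mmol·gDW⁻¹·h⁻¹
    #: exchange-reaction id -> (specific secretion rate q_p, concentration c_p)
    byproducts: dict[str, tuple[float, float]] = field(default_factory=dict)
    washout: bool = False

    def byproduct_rate(self, exchange_id: str) -> float:
        if exchange_id in self.byproducts:
            return self.byproducts[exchange_id][0]
        rev = exchange_id + "_REV"
        if rev in self.byproducts:
            return self.byproducts[rev][0]
        return 0.0


def _washout_point(D: float) -> ChemostatPoint:
    nan = float("nan")
    return ChemostatPoint(D=D, q_s=nan, c_x=nan, c_s=nan,
                          yield_gdw_per_mmol=nan, Y_xs=None,
                          OUR=nan, CPR=nan, washout=True)


def _find_gas_species(model: MetabolicModel, token: str) -> str | None:
    for mid in model.metabolites:
        base = mid.lower().rstrip("]").split("[")[0]
        if base == token or base == f"{token}_e" or base.startswith(f"{token}_"):
            return mid
    return None


def chemostat_point(model: MetabolicModel, D: float, feed: FeedSpec,
                    growth_reaction_id: str | None = None,
                    oxygen_species: str | None = None,
                    co2_species: str | None = None,
                    keep_species=MEDIUM_KEEP_SPECIES) -> ChemostatPoint:
    """Predict the steady state of a substrate-limited chemostat at
    dilution rate ``D`` (growth fixed to D, substrate uptake minimised).

    The medium supplies only the feed substrate plus the minimal-medium
    ``keep_species``: the uptake direction of every other exchange is
    closed, so the LP cannot consume species that are not fed.
    """
    if D <= 0:
        raise ValueError("dilution rate must be > 0")
    growth = growth_reaction_id or model.objective_reaction_id
    if growth is None:
        raise ValueError("no growth reaction specified")
    upt_id, upt_sign = resolve_uptake(model, feed.substrate_exchange_id)

    m = set_flux_bounds(model, growth, D, D)
    keep = {s.lower() for s in keep_species}
    feed_species = exchanged_species(m.reactions[upt_id])
    skip = {feed_species}
    if m.ec is not None:
        skip.add(m.ec.pool_metabolite_id)
        skip |= m.ec.enzyme_metabolite_ids
    for rxn in m.exchanges():
        sp = exchanged_species(rxn)
        if sp in skip or sp.lower() in keep or rxn.id == growth \
                or (m.ec is not None and rxn.id == m.ec.pool_exchange_id):
            continue
        close_uptake_direction(rxn, sp)
    sense = "min" if upt_sign > 0 else "max"  # minimise uptake magnitude
    sol = lexicographic_solve(m, [(upt_id, sense)])
    if not sol.ok:
        raise WashoutError(
            f"no steady state at D = {D} h⁻¹ (washout / above maximum "
            "growth rate)")

    q_s = upt_sign * sol.fluxes[upt_id]
    c_feed = feed.mmol_per_l
    c_x = D * c_feed / q_s if q_s > 0 else 0.0

    mw = feed.molar_mass
    if mw is None and feed.species is not None:
        mw = units.molar_mass(feed.species)
    Y_xs = 1000.0 * D / (q_s * mw) if (mw and q_s > 0) else None

    o2 = oxygen_species or _find_gas_species(m, "o2")
    co2 = co2_species or _find_gas_species(m, "co2")
    OUR = -medium_rate(m, sol.fluxes, o2) if o2 else 0.0
    CPR = medium_rate(m, sol.fluxes, co2) if co2 else 0.0

    substrate_species = exchanged_species(m.reactions[upt_id])
    skip = {substrate_species, o2, co2}
    growth_rxn = m.reactions[growth]
    if growth_rxn.is_exchange:  # toy-style biomass sink
        skip.add(exchanged_species(growth_rxn))
    if m.ec is not None:
        skip.add(m.ec.pool_metabolite_id)
        skip |= m.ec.enzyme_metabolite_ids
    byproducts: dict[str, tuple[float, float]] = {}
    for rxn in m.exchanges():
        sp = exchanged_species(rxn)
        if sp in skip:
            continue
        coef = rxn.stoich[sp]
        q_p = -coef * sol.fluxes.get(rxn.id, 0.0)  # >0: secreted
        if q_p > BYPRODUCT_THRESHOLD:
            byproducts[rxn.id] = (q_p, q_p * c_x / D)

    return ChemostatPoint(D=D, q_s=q_s, c_x=c_x, c_s=0.0,
                          yield_gdw_per_mmol=D / q_s if q_s > 0 else math.inf,
                          Y_xs=Y_xs, OUR=OUR, CPR=CPR, byproducts=byproducts)


def chemostat_sweep(model: MetabolicModel, D_grid, feed: FeedSpec,
                    **kwargs) -> list[ChemostatPoint]:
    """One :func:`chemostat_point` per dilution rate; infeasible rates are
    recorded as washout entries rather than silently dropped."""
    D_grid = list(D_grid)
    if not D_grid:
        raise ValueError("empty dilution-rate grid")
    if any(b <= a for a, b in zip(D_grid, D_grid[1:])):
        raise ValueError("dilution-rate grid must be strictly increasing")
    points = []
    for D in D_grid:
        try:
            points.append(chemostat_point(model, D, feed, **kwargs))
        except WashoutError:
            points.append(_washout_point(D))
    return points


def critical_dilution(points: list[ChemostatPoint], ethanol_exchange_id: str,
                      threshold: float = ETHANOL_ONSET_THRESHOLD,
                      ) -> float | None:
    """First dilution rate on the grid at which ethanol secretion exceeds
    ``threshold`` (grid convention: the reported D_crit is the first grid
    point strictly inside the overflow regime)."""
    for p in points:
        if p.washout:
            continue
        if p.byproduct_rate(ethanol_exchange_id) > threshold:
            return p.D
    return None


def sweep_to_records(points: list[ChemostatPoint]) -> list[dict]:
    """Flatten a sweep for CSV/DataFrame export."""
    rows = []
    for p in points:
        row = {"D": p.D, "q_s": p.q_s, "c_x": p.c_x, "c_s": p.c_s,
               "Y_xs": p.Y_xs, "OUR": p.OUR, "CPR": p.CPR,
               "washout": p.washout}
        for ex, (q_p, c_p) in sorted(p.byproducts.items()):
            row[f"q_{ex}"] = q_p
            row[f"c_{ex}"] = c_p
        rows.append(row)
    return rows
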