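"""Parametric toy enzyme-constrained models with closed-form behaviour.

The overflow toy distils the mechanism by which an enzyme-constrained model
predicts the Crabtree effect: a high-yield respiratory route competes with
a low-yield fermentative route for a bounded protein pool.  Respiration
gives more biomass per mmol substrate (y_r > y_f) but costs more protein
per unit growth (c_r/y_r > c_f/y_f), so at low growth the LP respires and
above a critical rate it progressively ferments — overflow emerges from the
pool bound alone, exactly as in the genome-scale case.

Because the toy has only two pathway degrees of freedom, every quantity the
simulation modules compute (q_s(μ), the fermentative flux, the critical
growth rate pool·y_r/c_r, chemostat concentrations) has a closed form,
recorded in :class:`ToyAnalytic` and used as an independent oracle.

Carbon bookkeeping is exact by construction: the substrate carries 6 carbon
atoms (glucose-like), ethanol 2, and biomass a fixed carbon content, with
CO2 closing every balance, so conservation checks must return zero
residuals.  Units follow the genome-scale convention (mmol·gDW⁻¹·h⁻¹, h⁻¹,
g·gDW⁻¹·h⁻¹) so fixtures exercise the same unit-handling code paths.

Uptake reactions carry zero pool cost by default (transporters are not part
of the protein pool in GECKO models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chemostat import ChemostatPoint, WashoutError
from .model import EcInfo, MetabolicModel, Metabolite, Reaction

_BIG = 1000.0


@dataclass
class OverflowToySpec:
    """Parameters of the two-route overflow toy.

    y_r, y_f: biomass yields (gDW·mmol⁻¹) of the respiratory and
    fermentative routes; c_r, c_f: protein-pool coefficients (g·h·mmol⁻¹);
    pool: pool exchange upper bound (g·gDW⁻¹·h⁻¹); q_max: substrate uptake
    cap (mmol·gDW⁻¹·h⁻¹).
    """

    y_r: float = 0.10
    y_f: float = 0.05
    c_r: float = 0.010
    c_f: float = 0.002
    pool: float = 0.02
    q_max: float = 10.0
    include_ethanol_assimilation: bool = False
    # carbon structure (exact bookkeeping): substrate 6 C, ethanol 2 C
    substrate_carbon: int = 6
    ethanol_carbon: int = 2
    biomass_carbon: float = 40.0     # C-mmol·gDW⁻¹
    # ethanol assimilation route (used when enabled)
    y_a: float = 0.025               # gDW·mmol⁻¹ ethanol
    c_a: float = 0.012               # g·h·mmol⁻¹ ethanol

    def __post_init__(self) -> None:
        if not (self.y_r > self.y_f > 0):
            raise ValueError("toy requires y_r > y_f > 0")
        if not (self.c_r > self.c_f > 0):
            raise ValueError("toy requires c_r > c_f > 0")
        if self.pool <= 0 or self.q_max <= 0:
            raise ValueError("pool and q_max must be > 0")
        if self.c_f / self.y_f >= self.c_r / self.y_r:
            raise ValueError(
                "overflow requires the fermentative route to be cheaper per "
                "unit growth (c_f/y_f < c_r/y_r)")
        if self.biomass_carbon * self.y_r > self.substrate_carbon:
            raise ValueError("respiratory biomass carbon exceeds substrate carbon")
        if (self.biomass_carbon * self.y_f + self.ethanol_carbon
                > self.substrate_carbon):
            raise ValueError("fermentative carbon products exceed substrate carbon")
        if self.include_ethanol_assimilation and \
                self.biomass_carbon * self.y_a > self.ethanol_carbon:
            raise ValueError("assimilation biomass carbon exceeds ethanol carbon")

    @property
    def carbon_atoms(self) -> dict[str, float]:
        """Carbon counts per tracked species (mmol basis)."""
        return {"s": float(self.substrate_carbon),
                "etoh": float(self.ethanol_carbon),
                "co2": 1.0, "o2": 0.0}


@dataclass
class ToyAnalytic:
    """Closed-form oracle for the overflow toy LP and chemostat."""

    spec: OverflowToySpec

    @property
    def mu_crit(self) -> float:
        """Growth rate at which the pool can no longer sustain pure
        respiration: pool·y_r/c_r (assuming the uptake cap is not hit
        first, which holds for all valid specs below mu_max)."""
        s = self.spec
        return min(s.pool * s.y_r / s.c_r, s.q_max * s.y_r)

    @property
    def mu_max(self) -> float:
        """Maximum growth over the 2-constraint polytope, by vertex
        enumeration of {v_r+v_f <= q_max, c_r v_r + c_f v_f <= pool}."""
        s = self.spec
        verts = [(0.0, 0.0),
                 (min(s.q_max, s.pool / s.c_r), 0.0),
                 (0.0, min(s.q_max, s.pool / s.c_f))]
        if s.c_r != s.c_f:
            v_r = (s.pool - s.c_f * s.q_max) / (s.c_r - s.c_f)
            v_f = s.q_max - v_r
            if v_r >= 0 and v_f >= 0:
                verts.append((v_r, v_f))
        return max(s.y_r * vr + s.y_f * vf for vr, vf in verts)

    def route_fluxes(self, mu: float) -> tuple[float, float]:
        """Uptake-minimising (v_resp, v_ferm) at growth rate ``mu``."""
        s = self.spec
        if mu > self.mu_max * (1 + 1e-12):
            raise WashoutError(f"mu = {mu} exceeds mu_max = {self.mu_max}")
        if mu <= s.pool * s.y_r / s.c_r:
            return mu / s.y_r, 0.0
        delta = s.y_r * s.c_f - s.y_f * s.c_r  # < 0 for valid specs
        v_r = (mu * s.c_f - s.pool * s.y_f) / delta
        v_f = (s.pool * s.y_r - mu * s.c_r) / delta
        if v_r < 0:  # pool so generous only fermentation is needed
            return 0.0, mu / s.y_f
        return v_r, v_f

    def q_s(self, mu: float) -> float:
        return sum(self.route_fluxes(mu))

    def v_ferm(self, mu: float) -> float:
        return self.route_fluxes(mu)[1]

    def chemostat_reference(self, D: float, feed_conc: float) -> ChemostatPoint:
        """Exact chemostat solution from the piecewise closed forms and the
        steady-state reactor balances (feed in mmol·l⁻¹)."""
        s = self.spec
        v_r, v_f = self.route_fluxes(D)  # raises WashoutError past mu_max
        q_s = v_r + v_f
        if q_s > s.q_max * (1 + 1e-12):
            raise WashoutError(f"required uptake {q_s} exceeds cap {s.q_max}")
        c_x = D * feed_conc / q_s
        co2_r = s.substrate_carbon - s.biomass_carbon * s.y_r
        co2_f = (s.substrate_carbon - s.biomass_carbon * s.y_f
                 - s.ethanol_carbon)
        byproducts = {}
        if v_f > 1e-12:
            byproducts["EX_etoh"] = (v_f, v_f * c_x / D)
        return ChemostatPoint(
            D=D, q_s=q_s, c_x=c_x, c_s=0.0,
            yield_gdw_per_mmol=D / q_s, Y_xs=None,
            OUR=co2_r * v_r, CPR=co2_r * v_r + co2_f * v_f,
            byproducts=byproducts)


def overflow_toy(spec: OverflowToySpec | None = None,
                 ) -> tuple[MetabolicModel, ToyAnalytic]:
    """Build the overflow toy ecGEM and its analytic oracle.

    Reactions: EX_S (pool-free uptake), R_resp, R_ferm, R_grow, EX_etoh,
    EX_o2_REV, EX_co2 and the protein-pool exchange; optionally an ethanol
    assimilation route (R_assim + EX_etoh_REV).
    """
    s = spec or OverflowToySpec()
    co2_r = s.substrate_carbon - s.biomass_carbon * s.y_r
    co2_f = s.substrate_carbon - s.biomass_carbon * s.y_f - s.ethanol_carbon

    mets = [Metabolite("s", "substrate"), Metabolite("etoh", "ethanol"),
            Metabolite("o2", "oxygen"), Metabolite("co2", "carbon dioxide"),
            Metabolite("x", "biomass precursor"),
            Metabolite("prot_pool", "protein pool")]
    rxns = [
        Reaction("EX_S", {"s": 1.0}, 0.0, s.q_max, name="substrate uptake"),
        Reaction("EX_o2_REV", {"o2": 1.0}, 0.0, _BIG, name="oxygen uptake"),
        Reaction("EX_etoh", {"etoh": -1.0}, 0.0, _BIG, name="ethanol secretion"),
        Reaction("EX_co2", {"co2": -1.0}, 0.0, _BIG, name="CO2 secretion"),
        Reaction("prot_pool_exchange", {"prot_pool": 1.0}, 0.0, s.pool),
        Reaction("R_resp",
                 {"s": -1.0, "o2": -co2_r, "prot_pool": -s.c_r,
                  "x": s.y_r, "co2": co2_r},
                 0.0, _BIG, name="respiratory route"),
        Reaction("R_ferm",
                 {"s": -1.0, "prot_pool": -s.c_f,
                  "x": s.y_f, "etoh": 1.0, "co2": co2_f},
                 0.0, _BIG, name="fermentative route"),
        Reaction("R_grow", {"x": -1.0}, 0.0, _BIG, name="growth"),
    ]
    pool_coeff = {"R_resp": s.c_r, "R_ferm": s.c_f}
    if s.include_ethanol_assimilation:
        co2_a = s.ethanol_carbon - s.biomass_carbon * s.y_a
        rxns.append(Reaction("EX_etoh_REV", {"etoh": 1.0}, 0.0, _BIG,
                             name="ethanol uptake"))
        rxns.append(Reaction("R_assim",
                             {"etoh": -1.0, "o2": -co2_a,
                              "prot_pool": -s.c_a,
                              "x": s.y_a, "co2": co2_a},
                             0.0, _BIG, name="ethanol assimilation"))
        pool_coeff["R_assim"] = s.c_a

    model = MetabolicModel(mets, rxns, objective_reaction_id="R_grow",
                           name="overflow_toy")
    model.ec = EcInfo(pool_exchange_id="prot_pool_exchange",
                      pool_metabolite_id="prot_pool",
                      pool_upper_bound=s.pool,
                      pool_coefficient=pool_coeff)
    return model, ToyAnalytic(s)


def plain_twin(model: MetabolicModel) -> MetabolicModel:
    """Strip the enzyme constraints: remove the pool metabolite, its
    exchange, and every pool draw, leaving the plain-GEM twin."""
    if model.ec is None:
        return model.copy()
    out = model.copy()
    pm = out.ec.pool_metabolite_id
    del out.reactions[out.ec.pool_exchange_id]
    for r in out.reactions.values():
        r.stoich.pop(pm, None)
    out.metabolites.pop(pm, None)
    for enz in out.ec.enzyme_metabolite_ids:
        out.metabolites.pop(enz, None)
    out.ec = None
    return out


# ---------------------------------------------------------------------------
# Dual-substrate toy (consumption-order mechanism)
# ---------------------------------------------------------------------------

@dataclass
class DualSubstrateToySpec:
    """Two substrates with a shared biomass yield but unequal protein
    costs; the LP's preference for the cheaper substrate makes the
    consumption order emerge whenever the pool binds."""

    cost_A: float = 0.008            # g·h·mmol⁻¹
    cost_B: float = 0.010
    yield_x: float = 0.10            # gDW·mmol⁻¹, shared
    pool: float = 0.02
    q_max_A: float = 10.0
    q_max_B: float = 10.0
    substrate_carbon: int = 6
    biomass_carbon: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.cost_A < self.cost_B):
            raise ValueError("toy requires 0 < cost_A < cost_B")
        if self.pool <= 0 or self.q_max_A <= 0 or self.q_max_B <= 0:
            raise ValueError("pool and uptake caps must be > 0")
        if self.biomass_carbon * self.yield_x > self.substrate_carbon:
            raise ValueError("biomass carbon exceeds substrate carbon")

    @property
    def pool_binds(self) -> bool:
        return self.pool < self.cost_A * self.q_max_A \
            + self.cost_B * self.q_max_B

    def max_growth_uptakes(self) -> tuple[float, float]:
        """LP optimum at saturating concentrations: fill the cheap
        substrate to its cap, then spend the remaining pool on the
        expensive one (closed-form greedy, optimal for equal yields)."""
        v_a = min(self.q_max_A, self.pool / self.cost_A)
        rest = self.pool - self.cost_A * v_a
        v_b = min(self.q_max_B, max(0.0, rest / self.cost_B))
        return v_a, v_b

    @property
    def carbon_atoms(self) -> dict[str, float]:
        return {"a": float(self.substrate_carbon),
                "b": float(self.substrate_carbon), "co2": 1.0}


def dual_substrate_toy(spec: DualSubstrateToySpec | None = None,
                       ) -> tuple[MetabolicModel, DualSubstrateToySpec]:
    s = spec or DualSubstrateToySpec()
    co2 = s.substrate_carbon - s.biomass_carbon * s.yield_x
    mets = [Metabolite("a", "substrate A"), Metabolite("b", "substrate B"),
            Metabolite("co2", "carbon dioxide"),
            Metabolite("x", "biomass precursor"),
            Metabolite("prot_pool", "protein pool")]
    rxns = [
        Reaction("EX_A", {"a": 1.0}, 0.0, s.q_max_A),
        Reaction("EX_B", {"b": 1.0}, 0.0, s.q_max_B),
        Reaction("EX_co2", {"co2": -1.0}, 0.0, _BIG),
        Reaction("prot_pool_exchange", {"prot_pool": 1.0}, 0.0, s.pool),
        Reaction("R_A", {"a": -1.0, "prot_pool": -s.cost_A,
                         "x": s.yield_x, "co2": co2}, 0.0, _BIG),
        Reaction("R_B", {"b": -1.0, "prot_pool": -s.cost_B,
                         "x": s.yield_x, "co2": co2}, 0.0, _BIG),
        Reaction("R_grow", {"x": -1.0}, 0.0, _BIG),
    ]
    model = MetabolicModel(mets, rxns, objective_reaction_id="R_grow",
                           name="dual_substrate_toy")
    model.ec = EcInfo(pool_exchange_id="prot_pool_exchange",
                      pool_metabolite_id="prot_pool",
                      pool_upper_bound=s.pool,
                      pool_coefficient={"R_A": s.cost_A, "R_B": s.cost_B})
    return model, s


def overflow_chemostat_reference(spec: OverflowToySpec, D: float,
                                 feed_conc: float) -> ChemostatPoint:
    """Closed-form chemostat oracle (raises WashoutError past mu_max)."""
    return ToyAnalytic(spec).chemostat_reference(D, feed_conc)


def fit_mu_crit(points, ethanol_exchange_id: str = "EX_etoh",
                threshold: float = 1e-4) -> float | None:
    """Recover the critical growth rate from a simulated sweep: the last
    grid point of the zero-ethanol region (its supremum on the grid)."""
    last_zero = None
    for p in points:
        if p.washout:
            continue
        if p.byproduct_rate(ethanol_exchange_id) <= threshold:
            last_zero = p.D
        else:
            break
    return last_zero
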