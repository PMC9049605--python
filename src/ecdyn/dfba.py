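"""Dynamic FBA for batch and fed-batch reactors.

The static-optimisation loop alternates three steps: (1) translate the
reactor state into flux bounds (Michaelis-Menten uptake kinetics, feed-phase
quasi-steady glucose balance, presence thresholds, regulation rules),
(2) solve the growth-maximising LP, and (3) integrate the extracellular mass
balances analytically over the step, assuming constant specific rates:

    B(t+dt)  = B·e^{μ·dt}                       (total biomass B = X·V)
    n_i(t+dt) = n_i + q_i·B·(e^{μ·dt}−1)/μ + F̄·c_feed,i·dt
    V(t+dt)  = V + ∫F dt

The integrator is exact for constant μ, so a batch with non-binding
constraints reproduces the exponential X₀·e^{μt} to machine precision.
A step that would drive a consumed species negative is rejected and retried
with a halved dt; amounts within the depletion tolerance are clamped to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from . import units
from .lp import solve_lp
from .model import (DEFAULT_FLUX_CAP, MetabolicModel,
                    close_uptake_direction, exchanged_species, medium_rate,
                    resolve_uptake, set_flux_bounds, species_exchange_map)

#: concentration above which a substrate counts as "present" (mmol·l⁻¹)
PRESENCE_THRESHOLD = 1e-6
#: amounts within this tolerance of zero are clamped (mmol)
DEPLETION_TOLERANCE = 1e-9
#: species whose liquid-phase accumulation is not tracked (gas exchange)
DEFAULT_GAS_SPECIES = ("o2", "co2")


class StepRejected(RuntimeError):
    """The proposed step would drive a species amount below -tolerance."""


def mm_uptake_bound(c: float, q_max: float, k_m: float) -> float:
    """Michaelis-Menten uptake bound q_max·c/(k_m + c), mmol·gDW⁻¹·h⁻¹."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if q_max <= 0 or k_m <= 0:
        raise ValueError("q_max and k_m must be > 0")
    return q_max * c / (k_m + c)


@dataclass
class UptakeKinetics:
    """How one substrate's uptake bound follows its reactor concentration.

    modes: ``michaelis_menten`` (bound = q_max·c/(k_m+c)),
    ``unconstrained_if_present`` (bound = q_max, typically the flux cap,
    whenever c exceeds the presence threshold), ``fixed`` (always q_max).
    """

    exchange_id: str
    q_max: float = DEFAULT_FLUX_CAP
    k_m: float = 0.28
    mode: str = "michaelis_menten"

    def __post_init__(self) -> None:
        if self.mode not in ("michaelis_menten", "unconstrained_if_present",
                             "fixed"):
            raise ValueError(f"unknown kinetics mode {self.mode!r}")
        if self.q_max <= 0:
            raise ValueError("q_max must be > 0")
        if self.mode == "michaelis_menten" and self.k_m <= 0:
            raise ValueError("k_m must be > 0 for Michaelis-Menten kinetics")


@dataclass
class RegulationRule:
    """Carbon-catabolite-repression style rule: while the inhibitor species
    exceeds ``threshold`` (mmol·l⁻¹), the inhibited uptake is closed."""

    inhibitor_species: str
    inhibited_exchange_id: str
    threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class FeedProfile:
    """Feed stream: constant F₀ or exponential F₀·e^{k(t−start)} (l·h⁻¹),
    delivering ``feed_conc`` (species -> mmol·l⁻¹)."""

    start_time: float
    rate: float
    feed_conc: dict[str, float]
    kind: str = "constant"
    k: float = 0.0
    stop_time: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("feed rate must be >= 0")
        if self.kind not in ("constant", "exponential"):
            raise ValueError(f"unknown feed kind {self.kind!r}")

    def F(self, t: float) -> float:
        if t < self.start_time:
            return 0.0
        if self.stop_time is not None and t >= self.stop_time:
            return 0.0
        if self.kind == "constant":
            return self.rate
        return self.rate * math.exp(self.k * (t - self.start_time))

    def volume_added(self, t: float, dt: float) -> float:
        """∫F over [t, t+dt], clipped to the active window (closed form)."""
        lo = max(t, self.start_time)
        hi = t + dt if self.stop_time is None else min(t + dt, self.stop_time)
        if hi <= lo:
            return 0.0
        if self.kind == "constant" or self.k == 0.0:
            return self.F(lo) * (hi - lo) if self.kind == "constant" \
                else self.rate * (hi - lo)
        a = self.rate / self.k
        return a * (math.exp(self.k * (hi - self.start_time))
                    - math.exp(self.k * (lo - self.start_time)))


@dataclass
class ReactorState:
    """Reactor contents at one instant: volume (l), biomass density
    (gDW·l⁻¹) and extracellular concentrations (mmol·l⁻¹)."""

    t: float
    V: float
    X: float
    conc: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError("reactor volume must be > 0")
        if self.X < 0:
            raise ValueError("biomass density must be >= 0")
        for sp, c in self.conc.items():
            if c < -DEPLETION_TOLERANCE:
                raise ValueError(f"negative concentration for {sp!r}: {c}")
            if c < 0:
                self.conc[sp] = 0.0

    @property
    def biomass(self) -> float:
        """Total biomass X·V, gDW."""
        return self.X * self.V


@dataclass
class Event:
    """A timed or state-triggered reactor intervention.

    actions: ``set_exchange_bound`` (params: reaction_id, lower, upper),
    ``add_mass`` (params: species, mmol or grams), ``start_feed``,
    ``stop_feed``.  ``flag`` is added to the state when the event fires.
    Each event fires at most once.
    """

    action: str
    time: float | None = None
    predicate: Callable[[ReactorState], bool] | None = None
    params: dict = field(default_factory=dict)
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ("set_exchange_bound", "add_mass",
                               "start_feed", "stop_feed"):
            raise ValueError(f"unknown event action {self.action!r}")
        if self.time is None and self.predicate is None:
            raise ValueError("event needs a trigger time or predicate")

    def due(self, state: ReactorState) -> bool:
        if self.time is not None:
            return state.t >= self.time - 1e-12
        return bool(self.predicate(state))


@dataclass
class StepRecord:
    t: float
    dt: float
    mu: float
    q: dict[str, float]            # species -> specific medium rate
    vol_added: float
    feed_mmol: dict[str, float]
    flags: set[str]


@dataclass
class Trajectory:
    states: list[ReactorState] = field(default_factory=list)
    steps: list[StepRecord] = field(default_factory=list)
    depletion_times: dict[str, float] = field(default_factory=dict)
    clamp_log: list[tuple[float, str]] = field(default_factory=list)

    @property
    def final(self) -> ReactorState:
        return self.states[-1]

    def to_dataframe(self):
        import pandas as pd

        species = sorted(self.states[0].conc) if self.states else []
        rows = []
        for i, s in enumerate(self.states):
            row = {"t": s.t, "V": s.V, "X": s.X}
            for sp in species:
                row[sp] = s.conc.get(sp, 0.0)
            if i < len(self.steps):
                row["mu"] = self.steps[i].mu
                for sp, q in self.steps[i].q.items():
                    row[f"q_{sp}"] = q
            row["flags"] = ";".join(sorted(s.flags))
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Constraint building
# ---------------------------------------------------------------------------

def _apply_uptake_bound(model: MetabolicModel, exchange_id: str,
                        bound: float) -> None:
    rid, sign = resolve_uptake(model, exchange_id)
    rxn = model.reactions[rid]
    if sign > 0:
        rxn.upper_bound = bound
        rxn.lower_bound = min(rxn.lower_bound, bound)
    else:
        rxn.lower_bound = -bound
        rxn.upper_bound = max(rxn.upper_bound, -bound)


def build_step_constraints(model: MetabolicModel, state: ReactorState,
                           kinetics: list[UptakeKinetics],
                           rules: list[RegulationRule] = (),
                           feed: FeedProfile | None = None,
                           feed_enabled: bool = True,
                           gas_species=DEFAULT_GAS_SPECIES,
                           exclude_species=()) -> MetabolicModel:
    """Translate the reactor state into uptake bounds on a model copy.

    During an active feed phase a substrate supplied by the feed is bound by
    the quasi-steady balance F(t)·c_feed/(X·V) — glucose is limiting and its
    reactor concentration negligible — instead of its concentration
    kinetics.  Regulation rules then close repressed uptakes, and the
    uptake of any tracked species that is absent from the reactor (below
    the presence threshold) is closed so the LP cannot import mass that is
    not there; gas species are exempt.
    """
    m = model.copy()
    feed_active = (feed is not None and feed_enabled
                   and feed.F(state.t) > 0)
    handled: set[str] = set()
    for kin in kinetics:
        rid, _ = resolve_uptake(m, kin.exchange_id)
        species = exchanged_species(m.reactions[rid])
        c = state.conc.get(species, 0.0)
        if feed_active and species in feed.feed_conc:
            if state.biomass <= 0:
                raise ValueError(
                    "feed-phase uptake bound undefined: no biomass in reactor")
            bound = feed.F(state.t) * feed.feed_conc[species] / state.biomass
        elif kin.mode == "michaelis_menten":
            bound = mm_uptake_bound(c, kin.q_max, kin.k_m)
        elif kin.mode == "unconstrained_if_present":
            bound = kin.q_max if c > PRESENCE_THRESHOLD else 0.0
        else:  # fixed
            bound = kin.q_max
        _apply_uptake_bound(m, kin.exchange_id, bound)
        handled.add(species)
    if feed_active:
        handled |= set(feed.feed_conc)
    skip = set(gas_species) | set(exclude_species) | handled
    for sp, rids in species_exchange_map(m).items():
        if sp in skip or state.conc.get(sp, 0.0) > PRESENCE_THRESHOLD:
            continue
        for rid in rids:
            close_uptake_direction(m.reactions[rid], sp)
    for rule in rules:
        if state.conc.get(rule.inhibitor_species, 0.0) > rule.threshold:
            _apply_uptake_bound(m, rule.inhibited_exchange_id, 0.0)
    return m


# ---------------------------------------------------------------------------
# Mass-balance integration
# ---------------------------------------------------------------------------

def integrate_step(state: ReactorState, mu: float, q: dict[str, float],
                   feed: FeedProfile | None, dt: float,
                   gas_species=DEFAULT_GAS_SPECIES,
                   feed_enabled: bool = True,
                   ) -> tuple[ReactorState, StepRecord, list[str]]:
    """Advance the reactor by ``dt`` hours at constant specific rates.

    ``q`` maps species to its specific medium rate (positive = secretion,
    negative = consumption, mmol·gDW⁻¹·h⁻¹).  Raises :class:`StepRejected`
    if a consumed species would fall below -tolerance.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    B = state.biomass
    growth = math.exp(mu * dt)
    factor = (growth - 1.0) / mu if abs(mu) > 1e-12 else dt

    vol_added = 0.0
    feed_mmol: dict[str, float] = {}
    if feed is not None and feed_enabled:
        vol_added = feed.volume_added(state.t, dt)
        feed_mmol = {sp: c * vol_added for sp, c in feed.feed_conc.items()}

    V2 = state.V + vol_added
    gases = set(gas_species)
    new_conc: dict[str, float] = {}
    clamps: list[str] = []
    for sp in set(state.conc) | set(q) - gases:
        if sp in gases:
            continue
        n = state.conc.get(sp, 0.0) * state.V
        n2 = n + q.get(sp, 0.0) * B * factor + feed_mmol.get(sp, 0.0)
        if n2 < -DEPLETION_TOLERANCE * max(1.0, abs(n)):
            raise StepRejected(
                f"species {sp!r} driven to {n2} mmol at t = {state.t + dt}")
        if n2 < 0.0:
            clamps.append(sp)
            n2 = 0.0
        new_conc[sp] = n2 / V2

    new_state = ReactorState(t=state.t + dt, V=V2, X=B * growth / V2,
                             conc=new_conc, flags=set(state.flags))
    rec = StepRecord(t=state.t, dt=dt, mu=mu, q=dict(q),
                     vol_added=vol_added, feed_mmol=feed_mmol,
                     flags=set(state.flags))
    return new_state, rec, clamps


# ---------------------------------------------------------------------------
# The dFBA loop
# ---------------------------------------------------------------------------

def simulate_dynamic(model: MetabolicModel, initial: ReactorState,
                     kinetics: list[UptakeKinetics],
                     events: list[Event] = (),
                     rules: list[RegulationRule] = (),
                     feed: FeedProfile | None = None,
                     dt: float = 0.01, t_end: float = 10.0,
                     growth_reaction_id: str | None = None,
                     gas_species=DEFAULT_GAS_SPECIES,
                     min_dt: float = 1e-6) -> Trajectory:
    """Run the dFBA loop until ``t_end``.

    Each iteration fires due events, rebuilds uptake constraints from the
    current state, maximises growth, and integrates the mass balances.  An
    infeasible LP is retried in maintenance mode (growth forced to 0); if
    still infeasible the state is frozen and flagged.
    """
    if dt <= 0 or dt > t_end:
        raise ValueError("require 0 < dt <= t_end")
    growth = growth_reaction_id or model.objective_reaction_id
    if growth is None:
        raise ValueError("no growth reaction specified")

    work = model.copy()
    state = ReactorState(t=initial.t, V=initial.V, X=initial.X,
                         conc=dict(initial.conc), flags=set(initial.flags))
    biomass_sp = exchanged_species(work.reactions[growth]) \
        if work.reactions[growth].is_exchange else None
    # track every boundary species the model can exchange
    for sp in species_exchange_map(work):
        if sp not in state.conc and sp not in set(gas_species) \
                and sp != biomass_sp:
            state.conc.setdefault(sp, 0.0)

    traj = Trajectory(states=[state])
    pending = list(events)
    feed_enabled = True

    while state.t < t_end - 1e-12:
        # -- events -------------------------------------------------------
        still_pending = []
        for ev in pending:
            if not ev.due(state):
                still_pending.append(ev)
                continue
            if ev.action == "set_exchange_bound":
                work = set_flux_bounds(work, ev.params["reaction_id"],
                                       ev.params.get("lower", 0.0),
                                       ev.params.get("upper", 0.0))
            elif ev.action == "add_mass":
                sp = ev.params["species"]
                if sp not in state.conc:
                    raise KeyError(f"event references unknown species {sp!r}")
                if "mmol" in ev.params:
                    amount = ev.params["mmol"]
                else:
                    mw = ev.params.get("molar_mass") or units.molar_mass(
                        ev.params.get("species_name", sp))
                    amount = ev.params["grams"] * 1000.0 / mw
                state.conc[sp] += amount / state.V
            elif ev.action == "start_feed":
                feed_enabled = True
            elif ev.action == "stop_feed":
                feed_enabled = False
            if ev.flag:
                state.flags.add(ev.flag)
        pending = still_pending

        # -- constraints + LP ---------------------------------------------
        step_model = build_step_constraints(
            work, state, kinetics, rules, feed, feed_enabled,
            gas_species=gas_species,
            exclude_species=() if biomass_sp is None else (biomass_sp,))
        sol = solve_lp(step_model, growth, "max")
        if not sol.ok:
            step_model = set_flux_bounds(step_model, growth, 0.0, 0.0)
            sol = solve_lp(step_model, growth, "max")
            if sol.ok:
                state.flags.add("maintenance_mode")
            else:
                state.flags.add("infeasible_frozen")
                frozen = ReactorState(t=t_end, V=state.V, X=state.X,
                                      conc=dict(state.conc),
                                      flags=set(state.flags))
                traj.states.append(frozen)
                return traj
        mu = sol.fluxes[growth]
        q = {sp: medium_rate(step_model, sol.fluxes, sp)
             for sp in species_exchange_map(step_model)}
        q.pop(biomass_sp, None)

        # -- integration with step rejection ------------------------------
        dt_step = min(dt, t_end - state.t)
        crossed = False
        dt_cross = _zero_crossing_dt(state, mu, q, feed, feed_enabled,
                                     gas_species, dt_step)
        if dt_cross is not None and min_dt <= dt_cross < dt_step:
            # land exactly on the depletion boundary (no mass clamped)
            dt_step = dt_cross
            crossed = True
        while True:
            try:
                new_state, rec, clamps = integrate_step(
                    state, mu, q, feed, dt_step, gas_species, feed_enabled)
                break
            except StepRejected:
                dt_cross = None if crossed else _zero_crossing_dt(
                    state, mu, q, feed, feed_enabled, gas_species, dt_step)
                if dt_cross is not None and min_dt <= dt_cross < dt_step:
                    # land exactly on the depletion boundary
                    dt_step = dt_cross
                    crossed = True
                    continue
                dt_step /= 2.0
                if dt_step < min_dt:
                    dt_step = min_dt
                    new_state, rec, clamps = _force_step(
                        state, mu, q, feed, dt_step, gas_species, feed_enabled)
                    break
        for sp in clamps:
            traj.clamp_log.append((new_state.t, sp))
        for sp, c_new in new_state.conc.items():
            if c_new <= PRESENCE_THRESHOLD \
                    and state.conc.get(sp, 0.0) > PRESENCE_THRESHOLD \
                    and sp not in traj.depletion_times:
                traj.depletion_times[sp] = new_state.t
                new_state.flags.add(f"{sp}_depleted")
        traj.steps.append(rec)
        traj.states.append(new_state)
        state = new_state
    return traj


def _zero_crossing_dt(state: ReactorState, mu: float, q: dict[str, float],
                      feed: FeedProfile | None, feed_enabled: bool,
                      gas_species, dt_max: float = math.inf) -> float | None:
    """Largest dt at which the first consumed species reaches exactly zero
    (closed form of the within-step balance); None when a feed stream also
    supplies a consumed species, in which case the caller falls back to
    step halving."""
    B = state.biomass
    if B <= 0:
        return None
    gases = set(gas_species)
    best = None
    for sp, qv in q.items():
        if qv >= -1e-10 or sp in gases:
            continue
        if (feed is not None and feed_enabled and sp in feed.feed_conc
                and feed.volume_added(state.t, min(dt_max, 1e6)) > 0):
            return None
        n = state.conc.get(sp, 0.0) * state.V
        target = n / (-qv * B)  # required (e^{mu dt}-1)/mu
        dt_sp = math.log1p(mu * target) / mu if abs(mu) > 1e-12 else target
        if best is None or dt_sp < best:
            best = dt_sp
    return best


def _force_step(state, mu, q, feed, dt, gas_species, feed_enabled):
    """Last-resort step at min_dt with clamping of any undershoot."""
    gases = set(gas_species)
    B = state.biomass
    growth = math.exp(mu * dt)
    factor = (growth - 1.0) / mu if abs(mu) > 1e-12 else dt
    vol_added = feed.volume_added(state.t, dt) if (feed and feed_enabled) else 0.0
    feed_mmol = {sp: c * vol_added for sp, c in feed.feed_conc.items()} \
        if (feed and feed_enabled) else {}
    V2 = state.V + vol_added
    new_conc, clamps = {}, []
    for sp in set(state.conc) | set(q):
        if sp in gases:
            continue
        n = state.conc.get(sp, 0.0) * state.V
        n2 = n + q.get(sp, 0.0) * B * factor + feed_mmol.get(sp, 0.0)
        if n2 < 0.0:
            clamps.append(sp)
            n2 = 0.0
        new_conc[sp] = n2 / V2
    new_state = ReactorState(t=state.t + dt, V=V2, X=B * growth / V2,
                             conc=new_conc, flags=set(state.flags))
    rec = StepRecord(t=state.t, dt=dt, mu=mu, q=dict(q),
                     vol_added=vol_added, feed_mmol=feed_mmol,
                     flags=set(state.flags))
    return new_state, rec, clamps


# ---------------------------------------------------------------------------
# Conservation QC
# ---------------------------------------------------------------------------

def carbon_recovery(trajectory: Trajectory, carbon_atoms: dict[str, float],
                    biomass_carbon: float) -> list[float]:
    """Per-step relative carbon-balance residual (a conservation check,
    not a result): (C produced − C consumed)/C consumed, where production
    counts biomass and accumulating species and consumption counts species
    drawn from the medium, net of feed additions.
    """
    residuals = []
    for i, rec in enumerate(trajectory.steps):
        s0, s1 = trajectory.states[i], trajectory.states[i + 1]
        inventory = biomass_carbon * s0.biomass + sum(
            carbon_atoms.get(sp, 0.0) * c * s0.V
            for sp, c in s0.conc.items())
        produced = biomass_carbon * (s1.biomass - s0.biomass)
        consumed = 0.0
        tracked = set(s0.conc) | set(s1.conc)
        for sp in tracked:
            if sp not in carbon_atoms:
                raise KeyError(f"no carbon count for tracked species {sp!r}")
            dn = (s1.conc.get(sp, 0.0) * s1.V - s0.conc.get(sp, 0.0) * s0.V
                  - rec.feed_mmol.get(sp, 0.0))
            if dn >= 0:
                produced += carbon_atoms[sp] * dn
            else:
                consumed += carbon_atoms[sp] * (-dn)
        # gas-phase CO2 leaves through q, not the liquid balance
        for sp, qv in rec.q.items():
            if sp in tracked:
                continue
            if sp not in carbon_atoms:
                raise KeyError(f"no carbon count for exchanged species {sp!r}")
            flow = qv * s0.biomass * rec.dt if rec.mu == 0 else \
                qv * s0.biomass * (math.exp(rec.mu * rec.dt) - 1.0) / rec.mu
            if flow >= 0:
                produced += carbon_atoms[sp] * flow
            else:
                consumed += carbon_atoms[sp] * (-flow)
        # steps with negligible turnover (solver noise after depletion)
        # are normalised against the system carbon inventory instead of
        # their own near-zero consumption
        denom = max(consumed, 1e-6 * inventory, 1e-12)
        residuals.append((produced - consumed) / denom)
    return residuals
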