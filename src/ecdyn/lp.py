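"""Linear programming on the stoichiometric network.

Flux balance analysis solves ``max/min v_obj  s.t.  S·v = 0, lb <= v <= ub``.
The solver backend is scipy's HiGHS, which is deterministic for a fixed
model, so identical inputs give identical solutions.

Alternate-optima contract: FBA optima are generically degenerate, so
downstream code must only rely on (a) objective values, (b) fluxes pinned by
lexicographic stages, or (c) sampling distributions — never on a single
solver-arbitrary flux value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel

#: solver tolerances, recorded in every solution for provenance
SOLVER_SETTINGS = {
    "backend": "scipy-highs",
    "feasibility_tolerance": 1e-9,
    "optimality_tolerance": 1e-9,
}

#: default relative tolerance when fixing a stage optimum in
#: lexicographic solves (absolute floor 1e-9); raw equality re-fixing causes
#: spurious infeasibility from solver round-off
DEFAULT_FIX_TOLERANCE = 1e-6


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    #: index of the failing stage for lexicographic solves
    failed_stage: int | None = None
    solver_settings: dict = field(default_factory=lambda: dict(SOLVER_SETTINGS))

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def _build_arrays(model: MetabolicModel):
    rids = model.reaction_ids
    mids = model.metabolite_ids
    ridx = {r: j for j, r in enumerate(rids)}
    midx = {m: i for i, m in enumerate(mids)}
    rows, cols, vals = [], [], []
    for rid, rxn in model.reactions.items():
        j = ridx[rid]
        for mid, coef in rxn.stoich.items():
            rows.append(midx[mid])
            cols.append(j)
            vals.append(coef)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(len(mids), len(rids)))
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    return rids, ridx, S, lb, ub


def _run(model: MetabolicModel, c: np.ndarray,
         lb: np.ndarray, ub: np.ndarray, S, rids) -> FluxSolution:
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]), method="highs",
        options={
            "primal_feasibility_tolerance":
                SOLVER_SETTINGS["feasibility_tolerance"],
            "dual_feasibility_tolerance":
                SOLVER_SETTINGS["optimality_tolerance"],
        },
    )
    if res.status == 0:
        return FluxSolution(status="optimal", objective_value=None,
                            fluxes=dict(zip(rids, res.x)))
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=None)
    return FluxSolution(status="infeasible", objective_value=None)


def solve_lp(model: MetabolicModel, objective_reaction_id: str | None = None,
             sense: str = "max") -> FluxSolution:
    """Single-objective FBA: optimise one reaction's flux at steady state."""
    obj = objective_reaction_id or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise KeyError(f"unknown objective reaction {obj!r}")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    rids, ridx, S, lb, ub = _build_arrays(model)
    c = np.zeros(len(rids))
    c[ridx[obj]] = -1.0 if sense == "max" else 1.0
    sol = _run(model, c, lb, ub, S, rids)
    if sol.ok:
        sol.objective_value = sol.fluxes[obj]
    return sol


def lexicographic_solve(model: MetabolicModel,
                        stages: list[tuple[str, str]],
                        fix_tolerance: float = DEFAULT_FIX_TOLERANCE,
                        ) -> FluxSolution:
    """Staged optimisation: solve stage 1, fix its objective near its
    optimum, re-solve stage 2 on the restricted polytope, and so on.

    ``stages`` is an ordered list of ``(reaction_id, sense)``.  The final
    solution is returned with ``objective_value`` of the last stage; an
    infeasible stage is reported with its index.
    """
    if not stages:
        raise ValueError("at least one stage required")
    rids, ridx, S, lb, ub = _build_arrays(model)
    lb, ub = lb.copy(), ub.copy()
    sol = None
    for k, (obj, sense) in enumerate(stages):
        if obj not in model.reactions:
            raise KeyError(f"unknown objective reaction {obj!r}")
        c = np.zeros(len(rids))
        c[ridx[obj]] = -1.0 if sense == "max" else 1.0
        sol = _run(model, c, lb, ub, S, rids)
        if not sol.ok:
            sol.failed_stage = k
            return sol
        opt = sol.fluxes[obj]
        sol.objective_value = opt
        if k < len(stages) - 1:
            slack = max(abs(opt) * fix_tolerance, 1e-9)
            j = ridx[obj]
            if sense == "max":
                lb[j] = max(lb[j], opt - slack)
            else:
                ub[j] = min(ub[j], opt + slack)
    return sol


def feasibility_check(model: MetabolicModel) -> str:
    """Report 'feasible' or 'infeasible' for the zero-objective LP."""
    rids, ridx, S, lb, ub = _build_arrays(model)
    sol = _run(model, np.zeros(len(rids)), lb, ub, S, rids)
    return "feasible" if sol.ok else "infeasible"
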