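"""Artificial-centering hit-and-run (ACHR) sampling of the flux polytope.

Instead of a single FBA optimum, sampling characterises the whole solution
space consistent with a physiological state.  The polytope is prepared the
way chemostat states are simulated: growth is fixed to the desired rate,
the substrate uptake is minimised and then confined to [v*, (1+slack)·v*]
(the lower arm of "minimal flux ± slack" is vacuous — fluxes below the
minimum are infeasible by definition), and numerically troublesome
reactions can be blocked.

ACHR walks inside the polytope: each move follows the direction from the
running centre to a randomly chosen warmup point.  Directions are
differences of feasible points, so S·d = 0 and steady state is preserved
exactly; only the admissible step interval against the bounds must be
computed.  Retained samples are validated against bounds and steady state,
and summarised as median ± median absolute deviation (MAD), optionally
relative to the substrate uptake flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lp import SOLVER_SETTINGS, _build_arrays, _run, lexicographic_solve
from .model import MetabolicModel, resolve_uptake, set_flux_bounds

#: feasibility tolerance for sample validation (bounds and |S·v|)
VALIDATION_TOLERANCE = 1e-6


@dataclass
class SamplingSetup:
    """Configuration of one sampling run (all randomness from ``seed``)."""

    growth_rate: float
    glucose_exchange_id: str
    slack: float = 0.10
    blocked_reaction_ids: tuple = ()
    seed: int = 0
    n_samples: int = 1000
    n_warmup: int = 2
    thinning: int = 100
    rescale_tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if self.n_warmup < 2:
            raise ValueError("n_warmup must be >= 2")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class SampleSet:
    """Flux samples (n_samples × n_reactions) with validity flags."""

    fluxes: np.ndarray
    reaction_ids: list[str]
    valid: np.ndarray | None = None
    setup: SamplingSetup | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.fluxes.shape[0]

    @property
    def retention(self) -> float:
        if self.valid is None:
            return 1.0
        return float(self.valid.mean()) if len(self.valid) else 0.0

    def column(self, reaction_id: str) -> np.ndarray:
        return self.fluxes[:, self.reaction_ids.index(reaction_id)]


@dataclass
class SampleSummary:
    """Per-reaction median and MAD of the valid samples."""

    table: "object"                  # pandas DataFrame
    n_valid: int
    n_excluded_relative: int = 0

    def __getitem__(self, reaction_id: str):
        return self.table.loc[reaction_id]


def prepare_sampling_model(model: MetabolicModel,
                           setup: SamplingSetup) -> MetabolicModel:
    """Fix growth, confine substrate uptake to [v*, (1+slack)·v*] around
    its minimum, and zero the blocked reactions."""
    growth = model.objective_reaction_id
    if growth is None:
        raise ValueError("model has no growth/objective reaction")
    m = set_flux_bounds(model, growth, setup.growth_rate, setup.growth_rate)
    rid, sign = resolve_uptake(m, setup.glucose_exchange_id)
    sense = "min" if sign > 0 else "max"
    sol = lexicographic_solve(m, [(rid, sense)])
    if not sol.ok:
        raise RuntimeError(
            f"growth rate {setup.growth_rate} infeasible: LP {sol.status}")
    v_star = sign * sol.fluxes[rid]
    if sign > 0:
        m = set_flux_bounds(m, rid, v_star, (1.0 + setup.slack) * v_star)
    else:
        m = set_flux_bounds(m, rid, -(1.0 + setup.slack) * v_star, -v_star)
    for bid in setup.blocked_reaction_ids:
        m = set_flux_bounds(m, bid, 0.0, 0.0)
    if setup.rescale_tolerance is not None:
        from .model import rescale_small_coefficients
        m, _ = rescale_small_coefficients(m, setup.rescale_tolerance)
    return m


def generate_warmup(model: MetabolicModel, n_warmup: int,
                    seed: int) -> np.ndarray:
    """Feasible flux vectors spanning the polytope, from ± coordinate
    objectives (exchanges and pool first) plus random dense objectives.

    Raises if fewer than 2 distinct points exist (degenerate polytope).
    """
    rids, ridx, S, lb, ub = _build_arrays(model)
    n = len(rids)
    rng = np.random.default_rng(seed)

    exch = [ridx[r.id] for r in model.exchanges()]
    coords = exch + [j for j in range(n) if j not in set(exch)]
    coords = coords[:max(min(len(coords), 200), (n_warmup + 1) // 2)]

    points = []
    for j in coords:
        for sgn in (-1.0, 1.0):
            c = np.zeros(n)
            c[j] = sgn
            sol = _run(model, c, lb, ub, S, rids)
            if sol.ok:
                points.append(np.array([sol.fluxes[r] for r in rids]))
    tries = 0
    while len(points) < n_warmup and tries < 10 * n_warmup:
        c = rng.standard_normal(n)
        sol = _run(model, c, lb, ub, S, rids)
        if sol.ok:
            points.append(np.array([sol.fluxes[r] for r in rids]))
        tries += 1
    if not points:
        raise RuntimeError("model infeasible: no warmup points")
    W = np.array(points)
    distinct = np.unique(np.round(W, 9), axis=0)
    if distinct.shape[0] < 2:
        raise RuntimeError(
            "degenerate polytope: fewer than 2 distinct warmup points")
    return W


def achr_sample(model: MetabolicModel, setup: SamplingSetup,
                prepared: bool = False) -> SampleSet:
    """Run the ACHR chain and return ``setup.n_samples`` samples (every
    ``setup.thinning``-th chain state), reproducibly for a fixed seed."""
    m = model if prepared else prepare_sampling_model(model, setup)
    rids, ridx, S, lb, ub = _build_arrays(m)
    W = generate_warmup(m, setup.n_warmup, setup.seed)
    rng = np.random.default_rng(setup.seed + 1)

    center = W.mean(axis=0)
    x = center.copy()
    n_points = W.shape[0]
    samples = np.empty((setup.n_samples, len(rids)))
    collected = 0
    it = 0
    degenerate_streak = 0
    max_iter = 1000 * setup.n_samples * setup.thinning + 10000
    while collected < setup.n_samples:
        if it > max_iter:
            raise RuntimeError(
                "ACHR aborted: admissible step interval repeatedly empty "
                f"(collected {collected}/{setup.n_samples})")
        it += 1
        d = W[rng.integers(W.shape[0])] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            degenerate_streak += 1
            if degenerate_streak > 10000:
                raise RuntimeError("ACHR aborted: degenerate directions")
            continue
        d /= norm
        mask = np.abs(d) > 1e-11
        if not mask.any():
            continue
        lo = (lb[mask] - x[mask]) / d[mask]
        hi = (ub[mask] - x[mask]) / d[mask]
        alpha_min = np.minimum(lo, hi).max()
        alpha_max = np.maximum(lo, hi).min()
        if alpha_max - alpha_min < 1e-12:
            degenerate_streak += 1
            continue
        degenerate_streak = 0
        alpha = rng.uniform(alpha_min, alpha_max)
        x = x + alpha * d
        n_points += 1
        center = center + (x - center) / n_points
        if it % setup.thinning == 0:
            samples[collected] = x
            collected += 1

    return SampleSet(
        fluxes=samples, reaction_ids=list(rids), setup=setup,
        provenance={"seed": setup.seed, "n_warmup_points": W.shape[0],
                    "thinning": setup.thinning,
                    "solver": dict(SOLVER_SETTINGS)})


def validate_samples(samples: SampleSet, model: MetabolicModel,
                     tolerance: float = VALIDATION_TOLERANCE) -> SampleSet:
    """Flag samples violating bounds or steady state beyond ``tolerance``
    and return the filtered set (retention recorded on the result)."""
    rids, ridx, S, lb, ub = _build_arrays(model)
    if samples.fluxes.shape[1] != len(rids):
        raise ValueError("sample matrix does not match model reactions")
    if samples.n == 0:
        return SampleSet(fluxes=samples.fluxes, reaction_ids=samples.reaction_ids,
                         valid=np.zeros(0, dtype=bool), setup=samples.setup,
                         provenance=dict(samples.provenance))
    order = [samples.reaction_ids.index(r) for r in rids]
    X = samples.fluxes[:, order]
    ok_bounds = ((X >= lb - tolerance) & (X <= ub + tolerance)).all(axis=1)
    ok_steady = np.abs(S @ X.T).max(axis=0) <= tolerance
    valid = ok_bounds & ok_steady
    prov = dict(samples.provenance)
    prov["retention"] = float(valid.mean())
    return SampleSet(fluxes=samples.fluxes[valid],
                     reaction_ids=list(samples.reaction_ids),
                     valid=valid, setup=samples.setup, provenance=prov)


def summarize_samples(samples: SampleSet,
                      glucose_exchange_id: str | None = None,
                      ) -> SampleSummary:
    """Median ± MAD per reaction; with a substrate exchange given, also the
    per-sample relative flux v_i / v_substrate (samples with zero substrate
    flux are excluded from the relative summary and counted)."""
    import pandas as pd

    X = samples.fluxes
    if X.shape[0] < 1:
        raise ValueError("no valid samples to summarise")
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    df = pd.DataFrame({"median": med, "mad": mad},
                      index=pd.Index(samples.reaction_ids, name="reaction"))
    excluded = 0
    if glucose_exchange_id is not None:
        j = samples.reaction_ids.index(glucose_exchange_id) \
            if glucose_exchange_id in samples.reaction_ids else None
        if j is None:
            raise KeyError(
                f"unknown reaction {glucose_exchange_id!r} in sample set")
        v_glc = X[:, j]
        nonzero = np.abs(v_glc) > 1e-12
        excluded = int((~nonzero).sum())
        if nonzero.any():
            R = X[nonzero] / v_glc[nonzero, None]
            rmed = np.median(R, axis=0)
            df["relative_median"] = rmed
            df["relative_mad"] = np.median(np.abs(R - rmed), axis=0)
    return SampleSummary(table=df, n_valid=X.shape[0],
                         n_excluded_relative=excluded)
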