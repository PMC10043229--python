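"""Linear-programming core: FBA, FVA, blocked reactions, production envelopes.

Flux balance analysis solves

    max/min  c . v
    s.t.     S v = 0,   lb <= v <= ub

with HiGHS (via :func:`scipy.optimize.linprog`).  All pipeline-level
quantities (essentiality calls, envelopes, FSEOF classification) are defined
through objective values or FVA ranges rather than a single optimal flux
vector: LP vertices are degenerate in genome-scale models and individual
optimal vectors are not reproducible across solvers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

#: default numerical tolerances (the primal feasibility tolerance applies to
#: |S v| and bound violations; the optimality tolerance to objective values)
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


class InfeasibleModelError(RuntimeError):
    """A constrained model admits no steady-state flux distribution."""


@dataclass(frozen=True)
class FluxSolution:
    status: str                      # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Optional[dict[str, float]]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class EnvelopePoint:
    growth: float
    min_production: float
    max_production: float


def _solve(model: MetabolicModel, c: np.ndarray, sense: str,
           extra_lb: Optional[dict[int, float]] = None,
           extra_ub: Optional[dict[int, float]] = None):
    """One LP solve; returns (status, objective, x)."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if extra_lb:
        for i, v in extra_lb.items():
            lb[i] = max(lb[i], v)
    if extra_ub:
        for i, v in extra_ub.items():
            ub[i] = min(ub[i], v)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status == 0:
        return "optimal", sign * res.fun, res.x
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise SolverError(f"HiGHS failed: status={res.status} ({res.message})")


def optimize(model: MetabolicModel, objective: Optional[str] = None,
             sense: str = "max") -> FluxSolution:
    """FBA: optimize one reaction's flux over the steady-state polytope.

    Returns a :class:`FluxSolution`; infeasibility is a status, not an
    exception.  When optimal, the returned flux vector is one (arbitrary)
    optimal vertex.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    rxn = objective if objective is not None else model.objective_reaction
    j = model.reaction_index(rxn)
    c = np.zeros(len(model.reactions))
    c[j] = 1.0
    status, obj, x = _solve(model, c, sense)
    if status != "optimal":
        return FluxSolution(status, None, None)
    fluxes = dict(zip(model.reaction_ids, (float(v) for v in x)))
    return FluxSolution("optimal", float(obj), fluxes)


def max_growth(model: MetabolicModel) -> float:
    """mu_max: maximal flux of the model's objective (biomass) reaction."""
    sol = optimize(model, model.objective_reaction, "max")
    if not sol.optimal:
        raise InfeasibleModelError(
            f"model {model.model_id!r} is {sol.status} when maximizing "
            f"{model.objective_reaction!r}")
    return sol.objective_value


def flux_variability(model: MetabolicModel,
                     reactions: Optional[Sequence[str]] = None,
                     biomass_fraction: float = 1.0) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux with growth held at a fraction of mu_max.

    mu_max is recomputed for the model as given (never cached across model
    mutations); the biomass reaction's lower bound is then raised to
    ``biomass_fraction * mu_max`` and each listed reaction is minimized and
    maximized in turn.
    """
    if not 0.0 <= biomass_fraction <= 1.0:
        raise ValueError(f"biomass_fraction must be in [0,1], got {biomass_fraction}")
    mu = max_growth(model)
    j_bio = model.reaction_index(model.objective_reaction)
    # back off marginally from mu_max so the constrained LP stays feasible
    # under solver round-off when biomass_fraction == 1
    floor = biomass_fraction * mu - (OPTIMALITY_TOL * max(1.0, abs(mu)))
    extra_lb = {j_bio: floor}
    if reactions is None:
        reactions = model.reaction_ids
    out = {}
    n = len(model.reactions)
    for rxn in reactions:
        j = model.reaction_index(rxn)
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, lo, _ = _solve(model, c, "min", extra_lb=extra_lb)
        hi_status, hi, _ = _solve(model, c, "max", extra_lb=extra_lb)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleModelError(
                f"FVA infeasible for {rxn!r} with growth >= "
                f"{biomass_fraction} * mu_max (mu_max={mu:.6g})")
        out[rxn] = (float(lo), float(hi))
    return out


def blocked_reactions(model: MetabolicModel, biomass_fraction: float = 0.2,
                      tol: float = OPTIMALITY_TOL) -> set[str]:
    """Reactions unable to carry flux when growth is held at the given
    fraction of mu_max (FVA min and max both within +-tol of zero)."""
    fva = flux_variability(model, None, biomass_fraction)
    return {rxn for rxn, (lo, hi) in fva.items()
            if abs(lo) <= tol and abs(hi) <= tol}


def production_envelope(model: MetabolicModel, target: str,
                        n_points: int = 20) -> list[EnvelopePoint]:
    """Feasible (growth, production) region boundary for a target reaction.

    Growth is fixed on a uniform grid over [0, mu_max]; at each grid point
    the target flux is minimized and maximized.  The first point (growth 0)
    therefore carries the unconstrained theoretical production maximum.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    j_t = model.reaction_index(target)   # raises KeyError for unknown target
    mu = max_growth(model)
    j_bio = model.reaction_index(model.objective_reaction)
    n = len(model.reactions)
    c = np.zeros(n)
    c[j_t] = 1.0
    points = []
    for g in np.linspace(0.0, mu, n_points):
        # fix growth to the grid value (within feasibility tolerance only,
        # so the pad cannot leak into reported production extremes)
        pad = FEASIBILITY_TOL * max(1.0, abs(mu))
        extra_lb = {j_bio: g - pad}
        extra_ub = {j_bio: g + pad}
        lo_status, lo, _ = _solve(model, c, "min", extra_lb, extra_ub)
        hi_status, hi, _ = _solve(model, c, "max", extra_lb, extra_ub)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleModelError(
                f"envelope infeasible at growth={g:.6g}")
        points.append(EnvelopePoint(float(g), float(lo), float(hi)))
    return points


def check_solution(model: MetabolicModel, fluxes: dict[str, float],
                   tol: float = 1e-6) -> bool:
    """True iff a flux vector satisfies S v = 0 and the bounds within tol."""
    v = np.array([fluxes[r] for r in model.reaction_ids])
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    return (np.abs(S @ v).max(initial=0.0) <= tol
            and bool(np.all(v >= lb - tol))
            and bool(np.all(v <= ub + tol)))


def fva_midpoints(model: MetabolicModel, reactions: Optional[Sequence[str]] = None,
                  biomass_fraction: float = 1.0) -> dict[str, float]:
    """Midpoint of each reaction's FVA interval — a degeneracy-robust
    single-number flux summary used by FSEOF, activity reports and scans."""
    fva = flux_variability(model, reactions, biomass_fraction)
    return {r: 0.5 * (lo + hi) for r, (lo, hi) in fva.items()}


def envelope_to_rows(points: Iterable[EnvelopePoint]) -> list[dict]:
    return [{"growth": p.growth, "min": p.min_production,
             "max": p.max_production} for p in points]
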