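"""Markov chain Monte Carlo sampling of the steady-state flux polytope.

Artificial-centering hit-and-run (ACHR): warmup points are optimal vertices
of randomized-objective FBA problems; the chain then repeatedly picks a
direction through the current running center (towards a random warmup
point), finds the feasible chord along that direction, and jumps to a
uniform point on the chord.  Directions are differences of feasible points,
so every iterate stays on the steady-state subspace S v = 0 exactly (up to
round-off, which is re-projected away periodically).

Used to compare regulation scenarios: a scenario forces a reaction's flux
to a multiple of a degeneracy-robust reference flux (up-regulation raises
the lower bound, down-regulation lowers the upper bound), and per-reaction
sample summaries are compared between control and scenario models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .lp import InfeasibleModelError, fva_midpoints
from .model import MetabolicModel, set_reaction_bounds

#: default warmup count = 2 x number of reactions, capped here
WARMUP_CAP = 500
DEFAULT_THINNING = 10
_DIR_TOL = 1e-10
_PROJECT_EVERY = 200


@dataclass(frozen=True)
class FluxSampleSet:
    samples: np.ndarray          # (n_samples, n_reactions)
    reaction_ids: tuple[str, ...]
    seed: int
    n_warmup: int
    thinning: int

    def column(self, rxn_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rxn_id)]

    def mean(self, rxn_id: str) -> float:
        return float(self.column(rxn_id).mean())


@dataclass(frozen=True)
class RegulationScenario:
    """Force a reaction to ``factor`` times a reference flux.

    factor > 1 raises the reaction's lower bound (over-expression);
    factor < 1 lowers its upper bound (down-regulation).  The reference is
    the control model's FVA-midpoint flux at 99% of maximal growth unless
    supplied explicitly.
    """
    reaction: str
    factor: float
    reference_flux: Optional[float] = None

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("scenario factor must be positive")


def reference_flux(model: MetabolicModel, rxn_id: str,
                   biomass_fraction: float = 0.99) -> float:
    """Degeneracy-robust single-number control flux for scenario scaling."""
    return fva_midpoints(model, [rxn_id], biomass_fraction)[rxn_id]


def apply_scenario(model: MetabolicModel,
                   scenario: RegulationScenario) -> MetabolicModel:
    """Derived model with the scenario bound applied.

    Raises :class:`InfeasibleModelError` if the bound leaves no feasible
    flux distribution.
    """
    ref = scenario.reference_flux
    if ref is None:
        ref = reference_flux(model, scenario.reaction)
    if ref <= 0:
        raise ValueError(
            f"reference flux for {scenario.reaction!r} must be positive "
            f"(got {ref!r}); supply reference_flux explicitly")
    rxn = model.reaction(scenario.reaction)
    target = scenario.factor * ref
    if scenario.factor >= 1.0 and target > rxn.upper_bound:
        raise InfeasibleModelError(
            f"scenario {scenario.reaction!r} x{scenario.factor}: forced "
            f"lower bound {target:.6g} exceeds the upper bound "
            f"{rxn.upper_bound:.6g}")
    if scenario.factor >= 1.0:
        derived = set_reaction_bounds(model, scenario.reaction,
                                      target, rxn.upper_bound)
    else:
        derived = set_reaction_bounds(model, scenario.reaction,
                                      rxn.lower_bound, target)
    # fail fast with the offending bound if the scenario is too aggressive
    S = derived.stoichiometric_matrix()
    lb, ub = derived.bounds_arrays()
    res = linprog(np.zeros(len(lb)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if res.status != 0:
        raise InfeasibleModelError(
            f"scenario {scenario.reaction!r} x{scenario.factor} "
            f"(bound {target:.6g}) makes the model infeasible")
    return derived


def _warmup_points(model: MetabolicModel, n_warmup: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Optimal vertices of randomized-objective LPs, spanning the polytope."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(lb)
    bounds = np.column_stack([lb, ub])
    points = []
    # axis-aligned objectives first (FVA-style corners), then random ones
    objectives = []
    for j in range(min(n, n_warmup // 2)):
        c = np.zeros(n)
        c[j] = 1.0
        objectives.append(c)
        objectives.append(-c)
    while len(objectives) < n_warmup:
        objectives.append(rng.standard_normal(n))
    for c in objectives[:n_warmup]:
        res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 2:
            raise InfeasibleModelError(
                f"model {model.model_id!r} infeasible; cannot sample")
        if res.status == 0:
            points.append(res.x)
    if not points:
        raise InfeasibleModelError("no warmup points could be generated")
    return np.array(points)


def _projector(S: sparse.csr_matrix) -> np.ndarray:
    """Orthogonal projector onto the null space of S (dense; models are
    small enough that this is cheap and exact to machine precision)."""
    A = S.toarray()
    # P = I - A^T (A A^T)^+ A
    pinv = np.linalg.pinv(A @ A.T)
    return np.eye(A.shape[1]) - A.T @ pinv @ A


def sample_fluxes(model: MetabolicModel, n: int, seed: int,
                  n_warmup: Optional[int] = None,
                  thinning: int = DEFAULT_THINNING) -> FluxSampleSet:
    """ACHR sampling of n flux vectors; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    n_rxn = len(model.reactions)
    if n_warmup is None:
        n_warmup = min(2 * n_rxn, WARMUP_CAP)
    warmup = _warmup_points(model, n_warmup, rng)
    lb, ub = model.bounds_arrays()
    S = model.stoichiometric_matrix()
    P = _projector(S)

    center = warmup.mean(axis=0)
    x = center.copy()
    n_seen = len(warmup)
    free = (ub - lb) > _DIR_TOL          # coordinates that can move at all

    samples = np.empty((n, n_rxn))
    collected = 0
    it = 0
    while collected < n:
        it += 1
        d = warmup[rng.integers(len(warmup))] - center
        d[~free] = 0.0
        norm = np.linalg.norm(d)
        if norm <= _DIR_TOL:
            continue
        d /= norm
        # feasible chord along d from the box bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            to_ub = (ub - x) / d
            to_lb = (lb - x) / d
        alphas_pos = np.concatenate([to_ub[d > _DIR_TOL], to_lb[d < -_DIR_TOL]])
        alphas_neg = np.concatenate([to_lb[d > _DIR_TOL], to_ub[d < -_DIR_TOL]])
        hi = alphas_pos.min(initial=np.inf)
        lo = alphas_neg.max(initial=-np.inf)
        if not np.isfinite(hi) or not np.isfinite(lo) or hi <= lo:
            continue
        x = x + rng.uniform(lo, hi) * d
        if it % _PROJECT_EVERY == 0:
            x = P @ x
            np.clip(x, lb, ub, out=x)
        # running center update (artificial centering)
        n_seen += 1
        center += (x - center) / n_seen
        if it % thinning == 0:
            samples[collected] = x
            collected += 1
    return FluxSampleSet(samples=samples,
                         reaction_ids=tuple(model.reaction_ids),
                         seed=seed, n_warmup=n_warmup, thinning=thinning)


def validate_samples(model: MetabolicModel, samples: FluxSampleSet,
                     tol: float = 1e-6) -> bool:
    """Every sample satisfies S v = 0 and the bounds within tolerance."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    V = samples.samples
    if np.abs(S @ V.T).max(initial=0.0) > tol:
        return False
    return bool(np.all(V >= lb - tol) and np.all(V <= ub + tol))


def save_samples(samples: FluxSampleSet, tsv_path, meta_path=None) -> None:
    """Write the sample matrix as TSV (header = reaction ids) with a JSON
    sidecar recording seed, warmup and thinning."""
    import json

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(samples.reaction_ids) + "\n")
        for row in samples.samples:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump({"seed": samples.seed, "n_warmup": samples.n_warmup,
                       "thinning": samples.thinning,
                       "n_samples": int(samples.samples.shape[0])}, fh,
                      indent=1, sort_keys=True)
            fh.write("\n")


def load_samples(tsv_path, meta_path) -> FluxSampleSet:
    import json

    with open(meta_path) as fh:
        meta = json.load(fh)
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [[float(v) for v in line.split("\t")] for line in fh]
    return FluxSampleSet(samples=np.array(rows), reaction_ids=tuple(header),
                         seed=meta["seed"], n_warmup=meta["n_warmup"],
                         thinning=meta["thinning"])


def compare_distributions(a: FluxSampleSet, b: FluxSampleSet,
                          reactions: Optional[Sequence[str]] = None
                          ) -> dict[str, dict]:
    """Per-reaction summary of two sample sets and the direction of shift.

    Shift direction is the sign of (mean_b - mean_a) when the difference
    exceeds twice the pooled standard error of the means, else "none".
    """
    shared = [r for r in a.reaction_ids if r in set(b.reaction_ids)]
    if reactions is not None:
        shared = [r for r in reactions if r in set(shared)]
    if not shared:
        raise ValueError("no shared reactions to compare")
    out = {}
    for r in shared:
        xa, xb = a.column(r), b.column(r)
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        se = float(np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb)))
        diff = mean_b - mean_a
        if abs(diff) > 2.0 * se:
            direction = "+" if diff > 0 else "-"
        else:
            direction = "none"
        out[r] = {
            "mean_a": mean_a, "mean_b": mean_b,
            "q05_a": float(np.quantile(xa, 0.05)),
            "q95_a": float(np.quantile(xa, 0.95)),
            "q05_b": float(np.quantile(xb, 0.05)),
            "q95_b": float(np.quantile(xb, 0.95)),
            "pooled_se": se, "shift": direction,
        }
    return out
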