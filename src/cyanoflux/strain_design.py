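"""Overexpression-target scanning (FSEOF) and knockout strain design.

FSEOF (flux scanning based on enforced objective flux) finds reactions
whose flux must rise as product formation is progressively enforced while
growth is held near-optimal; those are over-expression candidates, and
reactions whose flux falls are anti-targets (competing pathways).

Knockout design searches reaction-deletion sets that improve product
formation.  The classic bilevel formulations (OptKnock) and GPR-guided
local search (GDLS) are emulated here by exhaustive enumeration / greedy
beam search over a *reduced* candidate set — non-blocked, non-transport
reactions with known GPRs containing no essential gene — which is provably
equivalent on desk-scale instances and independent of MILP solver
behaviour.  A simplified multi-objective genetic algorithm searches for
growth-coupled designs on (growth, product, coupling strength), in the
spirit of Pareto-front coupling searches; coupling strength is the minimum
product flux attainable at maximal growth (zero means not growth-coupled).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .lp import (InfeasibleModelError, blocked_reactions, flux_variability,
                 fva_midpoints, max_growth, optimize)
from .model import MetabolicModel

DEFAULT_CLASSIFICATION_TOL = 1e-6
TRANSPORT_PATTERN = r"Transport"


# ---------------------------------------------------------------------------
# FSEOF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FSEOFConfig:
    max_product_fraction: float = 0.8   # enforce up to this fraction of the
                                        # theoretical product maximum
    min_biomass_fraction: float = 0.8   # growth kept above this x mu_max
    n_steps: int = 10
    classification_tol: float = DEFAULT_CLASSIFICATION_TOL

    def __post_init__(self):
        if not 0 < self.max_product_fraction <= 1:
            raise ValueError("max_product_fraction must be in (0, 1]")
        if not 0 < self.min_biomass_fraction <= 1:
            raise ValueError("min_biomass_fraction must be in (0, 1]")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass(frozen=True)
class FSEOFResult:
    target: str
    steps: tuple[float, ...]                      # enforced product fluxes
    profiles: dict[str, tuple[float, ...]]        # FVA-midpoint per step
    classification: dict[str, str]                # target|anti-target|unaffected

    @property
    def targets(self) -> list[str]:
        """Over-expression candidates, strongest flux increase first."""
        ts = [r for r, c in self.classification.items() if c == "target"]
        return sorted(ts, key=lambda r: (
            -(abs(self.profiles[r][-1]) - abs(self.profiles[r][0])), r))

    @property
    def anti_targets(self) -> list[str]:
        return sorted(r for r, c in self.classification.items()
                      if c == "anti-target")


def fseof(model: MetabolicModel, target: str,
          cfg: FSEOFConfig = FSEOFConfig()) -> FSEOFResult:
    """Scan per-reaction fluxes while the target flux is enforced stepwise.

    Growth is first held at ``min_biomass_fraction`` of mu_max; the
    target's theoretical maximum is computed *under that constraint* (so
    every enforcement step is feasible by construction) and the target's
    lower bound is then raised in ``n_steps`` uniform increments up to
    ``max_product_fraction`` of the maximum.  Per-step fluxes are
    FVA-interval midpoints (degeneracy proof).  A reaction is a *target*
    when |flux| increases monotonically with constant sign and total
    increase above tolerance; an *anti-target* when |flux| decreases
    monotonically likewise; anything else (including sign changes) is
    *unaffected*.
    """
    mu = max_growth(model)
    base = model.set_bounds(
        model.objective_reaction,
        max(model.reaction(model.objective_reaction).lower_bound,
            cfg.min_biomass_fraction * mu - 1e-9),
        model.reaction(model.objective_reaction).upper_bound)
    sol = optimize(base, target, "max")
    if not sol.optimal or sol.objective_value <= cfg.classification_tol:
        raise ValueError(
            f"target {target!r} carries no positive maximum with growth at "
            f"{cfg.min_biomass_fraction} of mu_max")
    v_max = sol.objective_value

    steps = []
    profiles: dict[str, list[float]] = {r: [] for r in model.reaction_ids}
    for k in range(1, cfg.n_steps + 1):
        enforced = (k / cfg.n_steps) * cfg.max_product_fraction * v_max
        steps.append(enforced)
        t_rxn = base.reaction(target)
        stepped = base.set_bounds(target, enforced,
                                  max(t_rxn.upper_bound, enforced))
        try:
            mids = fva_midpoints(stepped, None, 0.0)
        except InfeasibleModelError as exc:
            raise InfeasibleModelError(
                f"FSEOF infeasible at step {k} (enforced flux "
                f"{enforced:.6g})") from exc
        for r, v in mids.items():
            profiles[r].append(v)

    tol = cfg.classification_tol
    classification = {}
    for r, prof in profiles.items():
        a = np.asarray(prof)
        nz = a[np.abs(a) > tol]
        sign_constant = len(nz) == 0 or (np.all(nz > 0) or np.all(nz < 0))
        mags = np.abs(a)
        d = np.diff(mags)
        if sign_constant and np.all(d >= -tol) and mags[-1] - mags[0] >= tol:
            classification[r] = "target"
        elif sign_constant and np.all(d <= tol) and mags[0] - mags[-1] >= tol:
            classification[r] = "anti-target"
        else:
            classification[r] = "unaffected"
    return FSEOFResult(target=target, steps=tuple(steps),
                       profiles={r: tuple(p) for r, p in profiles.items()},
                       classification=classification)


# ---------------------------------------------------------------------------
# Model reduction for design
# ---------------------------------------------------------------------------

def reduce_for_design(model: MetabolicModel,
                      essential_genes: Iterable[str],
                      biomass_fraction: float = 0.2,
                      transport_pattern: str = TRANSPORT_PATTERN) -> list[str]:
    """Candidate knockout reactions after the standard reduction rules.

    Excluded: blocked reactions (FVA at the given growth fraction),
    reactions whose GPR contains an essential gene, transport and boundary
    reactions, orphan reactions (no GPR), and the biomass objective.
    """
    essential = set(essential_genes)
    blocked = blocked_reactions(model, biomass_fraction)
    pattern = re.compile(transport_pattern, re.IGNORECASE)
    out = []
    for r in model.reactions:
        if r.id == model.objective_reaction or r.id in blocked:
            continue
        if r.is_exchange or pattern.search(r.subsystem or ""):
            continue
        if r.gpr.is_empty():
            continue
        if r.gpr.genes() & essential:
            continue
        out.append(r.id)
    return out


# ---------------------------------------------------------------------------
# Design candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignCandidate:
    knockouts: frozenset[str]
    max_growth: float
    product_at_max_growth: float     # coupling strength
    max_product: float

    def sort_key(self) -> tuple:
        """Lexicographic ranking: coupling desc, product desc, fewer
        knockouts, then ids."""
        return (-self.product_at_max_growth, -self.max_product,
                len(self.knockouts), tuple(sorted(self.knockouts)))


def coupling_strength(model: MetabolicModel, target: str) -> float:
    """Minimum target flux with growth fixed at mu_max (FVA lower bound at
    biomass fraction 1).  Positive beyond tolerance = growth-coupled."""
    lo, _hi = flux_variability(model, [target], 1.0)[target]
    return lo


def evaluate_design(model: MetabolicModel, target: str,
                    knockouts: Iterable[str],
                    min_growth: float = 0.0) -> Optional[DesignCandidate]:
    """Metrics of one knockout set; None if it cannot reach min_growth.

    All metrics are recomputed from the model and knockout set alone.
    """
    ko = frozenset(knockouts)
    mutant = model.knock_out_reactions(ko)
    sol = optimize(mutant, mutant.objective_reaction, "max")
    mu = sol.objective_value if sol.optimal else 0.0
    if not sol.optimal or mu < min_growth:
        return None
    coupling = coupling_strength(mutant, target)
    # production capacity subject to the same viability floor
    j_bio = mutant.reaction(mutant.objective_reaction)
    capped = mutant.set_bounds(mutant.objective_reaction,
                               max(j_bio.lower_bound, min_growth),
                               j_bio.upper_bound)
    prod = optimize(capped, target, "max")
    max_product = prod.objective_value if prod.optimal else 0.0
    return DesignCandidate(ko, mu, coupling, max_product)


def enumerate_knockouts(model: MetabolicModel, target: str, k_max: int,
                        candidates: Sequence[str], min_growth: float = 0.0,
                        budget: int = 20000, beam_width: int = 10
                        ) -> tuple[list[DesignCandidate], dict]:
    """Ranked knockout designs of size <= k_max from the candidate set.

    Exhaustive when the number of subsets fits the evaluation budget,
    otherwise greedy beam search (deterministic).  Returns the ranked list
    and metadata recording which mode ran.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if not candidates:
        raise ValueError("candidate set is empty")
    n_subsets = sum(math.comb(len(candidates), k)
                    for k in range(1, k_max + 1))
    meta = {"mode": "exhaustive", "n_candidates": len(candidates),
            "k_max": k_max, "evaluated": 0}
    results: list[DesignCandidate] = []
    cache: dict[frozenset, Optional[DesignCandidate]] = {}

    def evaluate(ko: frozenset) -> Optional[DesignCandidate]:
        if ko not in cache:
            cache[ko] = evaluate_design(model, target, ko, min_growth)
            meta["evaluated"] += 1
        return cache[ko]

    if n_subsets <= budget:
        for k in range(1, k_max + 1):
            for combo in itertools.combinations(sorted(candidates), k):
                cand = evaluate(frozenset(combo))
                if cand is not None:
                    results.append(cand)
    else:
        meta["mode"] = "beam"
        meta["notice"] = (f"{n_subsets} subsets exceed budget {budget}; "
                          "greedy beam search used")
        beam: list[frozenset] = [frozenset()]
        for _ in range(k_max):
            scored = []
            for base in beam:
                for c in sorted(set(candidates) - base):
                    ko = base | {c}
                    cand = evaluate(ko)
                    if cand is not None:
                        scored.append(cand)
            if not scored:
                break
            scored.sort(key=lambda c: c.sort_key())
            results.extend(scored)
            seen = set()
            beam = []
            for cand in scored:
                if cand.knockouts not in seen:
                    seen.add(cand.knockouts)
                    beam.append(cand.knockouts)
                if len(beam) >= beam_width:
                    break
    unique = {c.knockouts: c for c in results}
    ranked = sorted(unique.values(), key=lambda c: c.sort_key())
    return ranked, meta


# ---------------------------------------------------------------------------
# Genetic-algorithm coupling search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAParams:
    """Parameters of the coupling search (names mirror the common
    gcFront-style configuration keys)."""
    biomass_reaction: str = ""
    min_growth: float = 1e-3
    max_knockouts: int = 30          # maxreductionsize
    ignore_reactions: tuple[str, ...] = ()
    population_size: int = 1000      # popsize
    generation_limit: int = 100      # genlimit
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_knockouts < 1:
            raise ValueError("max_knockouts must be >= 1")


def _dominates(a: DesignCandidate, b: DesignCandidate, tol: float = 1e-9) -> bool:
    """Pareto dominance on (max_growth, max_product, coupling strength)."""
    av = (a.max_growth, a.max_product, a.product_at_max_growth)
    bv = (b.max_growth, b.max_product, b.product_at_max_growth)
    return all(x >= y - tol for x, y in zip(av, bv)) and \
        any(x > y + tol for x, y in zip(av, bv))


def pareto_front(cands: Iterable[DesignCandidate]) -> list[DesignCandidate]:
    cands = list({c.knockouts: c for c in cands}.values())
    front = [c for c in cands
             if not any(_dominates(o, c) for o in cands if o is not c)]
    return sorted(front, key=lambda c: c.sort_key())


def ga_coupling_search(model: MetabolicModel, target: str, params: GAParams,
                       candidates: Optional[Sequence[str]] = None,
                       essential_genes: Optional[Iterable[str]] = None
                       ) -> list[DesignCandidate]:
    """Seeded genetic algorithm over knockout bit-vectors.

    Fitness is the objective triple (max growth, max product, coupling
    strength) under non-dominated sorting; individuals below ``min_growth``
    are infeasible.  Internals are fixed: tournament selection of size 2,
    uniform crossover p=0.5, per-bit mutation 1/n_candidates.  Returns the
    non-dominated front of all feasible designs evaluated; reproducible
    for a fixed seed.
    """
    if candidates is None:
        if essential_genes is None:
            raise ValueError("supply candidates or essential_genes")
        candidates = reduce_for_design(model, essential_genes)
    pool = [c for c in candidates if c not in set(params.ignore_reactions)]
    if not pool:
        raise ValueError("candidate pool is empty")
    pool = sorted(pool)
    n = len(pool)
    rng = np.random.default_rng(params.seed)
    pop_size = params.population_size
    p_mut = 1.0 / n

    cache: dict[frozenset, Optional[DesignCandidate]] = {}

    def evaluate(bits: np.ndarray) -> Optional[DesignCandidate]:
        ko = frozenset(p for p, b in zip(pool, bits) if b)
        if ko not in cache:
            cache[ko] = evaluate_design(model, target, ko, params.min_growth)
        return cache[ko]

    def repair(bits: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(bits)
        if len(on) > params.max_knockouts:
            off = rng.choice(on, size=len(on) - params.max_knockouts,
                             replace=False)
            bits = bits.copy()
            bits[off] = 0
        return bits

    def rank_key(bits: np.ndarray) -> tuple:
        cand = evaluate(bits)
        if cand is None:
            return (1, 0.0, 0.0, 0.0)      # infeasible: dominated by all
        return (0, -cand.product_at_max_growth, -cand.max_product,
                -cand.max_growth)

    # initial population: wild type, singles, then random sparse vectors
    population = [np.zeros(n, dtype=np.int8)]
    for i in range(min(n, pop_size - 1)):
        bits = np.zeros(n, dtype=np.int8)
        bits[i] = 1
        population.append(bits)
    while len(population) < pop_size:
        k = int(rng.integers(1, params.max_knockouts + 1))
        bits = np.zeros(n, dtype=np.int8)
        bits[rng.choice(n, size=min(k, n), replace=False)] = 1
        population.append(bits)

    for _ in range(params.generation_limit):
        keys = [rank_key(b) for b in population]
        children = []
        while len(children) < pop_size:
            picks = rng.integers(len(population), size=4)
            pa = population[picks[0]] if keys[picks[0]] <= keys[picks[1]] \
                else population[picks[1]]
            pb = population[picks[2]] if keys[picks[2]] <= keys[picks[3]] \
                else population[picks[3]]
            mask = rng.random(n) < 0.5
            child = np.where(mask, pa, pb).astype(np.int8)
            flip = rng.random(n) < p_mut
            child = np.where(flip, 1 - child, child).astype(np.int8)
            children.append(repair(child))
        population = children

    feasible = [c for c in cache.values() if c is not None]
    if not feasible:
        return []
    return pareto_front(feasible)
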