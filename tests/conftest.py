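"""Shared fixtures and independent oracles for the test suite.

Two oracles cross-check the LP engine:

* a brute-force vertex-enumeration solver (``vertex_optimize``) that finds
  the optimum of tiny LPs by enumerating basic feasible points of
  {S v = 0, lb <= v <= ub} — independent of any LP library;
* COBRApy (built from the same model description) as an independent
  full-stack implementation for FBA/FVA/essentiality comparisons.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cyanoflux import (apply_condition, make_chain_toy, make_toy_phototroph,
                       make_two_sink_toy, miniphoto_condition_specs)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def miniphoto():
    return make_toy_phototroph()


@pytest.fixture(scope="session")
def chain():
    return make_chain_toy()


@pytest.fixture(scope="session")
def two_sink():
    return make_two_sink_toy()


@pytest.fixture(scope="session")
def condition_models(miniphoto):
    specs = miniphoto_condition_specs()
    return {name: apply_condition(miniphoto, spec)
            for name, spec in specs.items()}


# ---------------------------------------------------------------------------
# Oracle 1: brute-force vertex enumeration
# ---------------------------------------------------------------------------

def vertex_optimize(model, objective: str, sense: str = "max",
                    tol: float = 1e-9):
    """Optimum of max/min v_objective over {S v = 0, lb <= v <= ub} found by
    enumerating candidate vertices (coordinates fixed at bounds, remainder
    solved from the equality system).  Exponential; fixtures only."""
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    j_obj = model.reaction_index(objective)
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - r
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(choice) if fixed else \
                np.zeros(S.shape[0])
            if free:
                sol, res, rank, _ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                if rank < len(free):
                    continue            # underdetermined basis: not a vertex
                v = np.empty(n)
                v[list(fixed)] = choice
                v[free] = sol
            else:
                v = np.array(choice)
            if np.abs(S @ v).max(initial=0.0) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = v[j_obj]
            if best is None or (sense == "max" and val > best) or \
                    (sense == "min" and val < best):
                best = val
    return best


# ---------------------------------------------------------------------------
# Oracle 2: COBRApy twin of a model
# ---------------------------------------------------------------------------

def to_cobra(model):
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    for g in model.genes:
        cm.genes.add(cobra.Gene(g))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                            upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        gpr = r.gpr.to_string()
        if gpr:
            cr.gene_reaction_rule = gpr
    cm.objective = model.objective_reaction
    return cm
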