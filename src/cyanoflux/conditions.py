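"""Condition-specific model construction and comparison.

A :class:`ConditionSpec` carries named bound overrides (with an explicit
uptake-orientation flag per reaction, because published bound tables are
printed as positive pairs while exchange fluxes here are negative for
uptake) and the biomass variant active under that condition.  Applying a
spec yields a derived model with the overrides in place, competing biomass
variants closed, and the objective switched.

On top of condition models this module provides the production-envelope
comparison across conditions, the photosynthetic-activity report
(photosystem fluxes, oxygen exchange and photon uptake normalised to the
photoautotrophic baseline), and a forced-overexpression scan reporting
growth, product formation and companion fluxes per enforcement level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .lp import (InfeasibleModelError, fva_midpoints, max_growth, optimize,
                 production_envelope)
from .model import MetabolicModel, set_reaction_bounds

CONDITION_NAMES = ("photoautotrophy", "acetate_photomixotrophy",
                   "glucose_photomixotrophy")


@dataclass(frozen=True)
class BoundOverride:
    """One reaction's condition bounds.

    ``orientation`` is ``"forward"`` when the printed (lb, ub) pair applies
    directly (reaction written in its uptake/consumption direction), or
    ``"uptake_negative"`` when the pair states uptake *magnitudes* for an
    exchange whose uptake flux is negative — (L, U) then maps to (-U, -L).
    """
    reaction: str
    lb: float
    ub: float
    orientation: str = "forward"

    def resolved(self) -> tuple[float, float]:
        if self.orientation == "forward":
            return (self.lb, self.ub)
        if self.orientation == "uptake_negative":
            return (-self.ub, -self.lb)
        raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    biomass_reaction: str
    overrides: tuple[BoundOverride, ...] = ()
    #: biomass variants to close (bounds 0) when not selected
    biomass_variants: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "overrides", tuple(self.overrides))
        object.__setattr__(self, "biomass_variants",
                           tuple(self.biomass_variants))


def apply_condition(model: MetabolicModel,
                    spec: ConditionSpec) -> MetabolicModel:
    """Derived condition-specific model.

    Overrides are absolute (they replace, not tighten, existing bounds);
    non-selected biomass variants are closed and the objective is set to
    the spec's biomass reaction.  Raises if the result cannot grow.
    """
    out = model
    for ov in spec.overrides:
        lb, ub = ov.resolved()
        out = set_reaction_bounds(out, ov.reaction, lb, ub)
    for variant in spec.biomass_variants:
        if variant != spec.biomass_reaction:
            out = set_reaction_bounds(out, variant, 0.0, 0.0)
    bio = out.reaction(spec.biomass_reaction)
    if bio.upper_bound <= 0:
        out = set_reaction_bounds(out, spec.biomass_reaction, 0.0, 1000.0)
    out = out.set_objective(spec.biomass_reaction)
    sol = optimize(out)
    if not sol.optimal:
        raise InfeasibleModelError(
            f"condition {spec.name!r} leaves the model {sol.status}")
    return out


# -- MiniPhoto condition specs (bounds after the published condition table;
#    uptake magnitudes forced through the transporter in its forward
#    direction and matched at the exchange with the negative-uptake flag) --

def miniphoto_condition_specs() -> dict[str, ConditionSpec]:
    variants = ("BOF_photoautotrophy", "BOF_acetate_photomixotrophy",
                "BOF_glucose_photomixotrophy")
    return {
        "photoautotrophy": ConditionSpec(
            name="photoautotrophy",
            biomass_reaction="BOF_photoautotrophy",
            biomass_variants=variants,
            overrides=(BoundOverride("RBPCcx", 1.46, 1000.0),
                       BoundOverride("ACtex", 0.0, 1000.0),
                       BoundOverride("GLCtex", 0.0, 1000.0))),
        "acetate_photomixotrophy": ConditionSpec(
            name="acetate_photomixotrophy",
            biomass_reaction="BOF_acetate_photomixotrophy",
            biomass_variants=variants,
            overrides=(BoundOverride("RBPCcx", 1.8, 1000.0),
                       BoundOverride("ACtex", 0.257, 1000.0),
                       BoundOverride("EX_ac", 0.257, 1000.0,
                                     orientation="uptake_negative"),
                       BoundOverride("GLCtex", 0.0, 1000.0))),
        "glucose_photomixotrophy": ConditionSpec(
            name="glucose_photomixotrophy",
            biomass_reaction="BOF_glucose_photomixotrophy",
            biomass_variants=variants,
            overrides=(BoundOverride("RBPCcx", 1.73, 1000.0),
                       BoundOverride("GLCtex", 0.175, 1000.0),
                       BoundOverride("EX_glc", 0.175, 1000.0,
                                     orientation="uptake_negative"),
                       BoundOverride("ACtex", 0.0, 1000.0))),
    }


# ---------------------------------------------------------------------------
# Cross-condition comparisons
# ---------------------------------------------------------------------------

def compare_envelopes(models: dict[str, MetabolicModel], target: str,
                      n_points: int = 20) -> dict[str, dict]:
    """Per-condition production envelope plus (mu_max, max product)."""
    if len(models) < 2:
        raise ValueError("need at least two conditions to compare")
    out = {}
    for name, model in models.items():
        env = production_envelope(model, target, n_points)
        sol = optimize(model, target, "max")
        out[name] = {
            "envelope": env,
            "mu_max": max_growth(model),
            "max_product": sol.objective_value if sol.optimal else 0.0,
        }
    return out


@dataclass(frozen=True)
class ActivityReport:
    """Per-condition FVA-midpoint fluxes at mu_max, normalised to the
    baseline condition; ratios with a zero baseline are None."""
    baseline: str
    fluxes: dict[str, dict[str, float]]           # condition -> rxn -> flux
    ratios: dict[str, dict[str, Optional[float]]]


def photosynthetic_activity(models: dict[str, MetabolicModel],
                            reactions: Sequence[str],
                            baseline: str = "photoautotrophy",
                            zero_tol: float = 1e-6) -> ActivityReport:
    if baseline not in models:
        raise ValueError(f"baseline condition {baseline!r} missing")
    fluxes = {}
    for name, model in models.items():
        fluxes[name] = fva_midpoints(model, list(reactions), 1.0)
    base = fluxes[baseline]
    ratios: dict[str, dict[str, Optional[float]]] = {}
    for name in models:
        ratios[name] = {}
        for r in reactions:
            if abs(base[r]) <= zero_tol:
                ratios[name][r] = None          # undefined, not infinity
            else:
                ratios[name][r] = fluxes[name][r] / base[r]
    return ActivityReport(baseline=baseline, fluxes=fluxes, ratios=ratios)


def overexpression_scan(model: MetabolicModel, reaction: str,
                        levels: Sequence[float], target: str,
                        report_reactions: Sequence[str] = ()
                        ) -> list[dict]:
    """Force ``reaction`` >= level and report growth, target production at
    maximal growth, and FVA midpoints of companion reactions.

    Infeasible levels are recorded in-table rather than raised.
    """
    rows = []
    for level in levels:
        rxn = model.reaction(reaction)
        stepped = set_reaction_bounds(model, reaction, level,
                                      max(rxn.upper_bound, level))
        row: dict = {"level": level}
        try:
            mu = max_growth(stepped)
            mids = fva_midpoints(stepped,
                                 [target, *report_reactions], 1.0)
        except InfeasibleModelError:
            row["feasible"] = False
            rows.append(row)
            continue
        row["feasible"] = True
        row["mu_max"] = mu
        row["target_at_mu_max"] = mids[target]
        for r in report_reactions:
            row[r] = mids[r]
        rows.append(row)
    return rows
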