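"""Pipeline orchestration: stages, config, manifest and report bundling.

A :class:`PipelineConfig` (loadable from YAML/JSON) names the model, the
target reaction, the experimental label table, condition specs and stage
parameters.  :func:`run_pipeline` executes the requested stages in
dependency order and writes per-stage TSV/JSON reports plus a manifest
(package version, config hash, seed, per-stage wall time) into the output
directory.  Reruns with identical config and seed reproduce all
deterministic outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .conditions import (BoundOverride, ConditionSpec, apply_condition,
                         compare_envelopes, miniphoto_condition_specs,
                         overexpression_scan, photosynthetic_activity)
from .essentiality import (classify_essential, compute_stats, confusion,
                           read_label_table, screen_report_rows,
                           single_gene_deletion)
from .lp import optimize, production_envelope
from .model import read_model_json
from .sampling import (RegulationScenario, apply_scenario,
                       compare_distributions, sample_fluxes)
from .strain_design import (FSEOFConfig, GAParams, enumerate_knockouts,
                            fseof, ga_coupling_search, reduce_for_design)

ALL_STAGES = ("fba", "essentiality", "envelope", "fseof", "design", "ga",
              "sample", "conditions", "scan")


@dataclass
class PipelineConfig:
    model_path: str
    out_dir: str
    target: str = "DM_ALA"
    labels_path: Optional[str] = None
    seed: int = 0
    essentiality_threshold: float = 1e-3
    blocked_biomass_fraction: float = 0.2
    envelope_points: int = 20
    fseof: FSEOFConfig = field(default_factory=FSEOFConfig)
    ga: GAParams = field(default_factory=lambda: GAParams(
        population_size=40, generation_limit=25, max_knockouts=5))
    design_k_max: int = 2
    sample_n: int = 500
    scan_reaction: str = "DES12"
    scan_levels: tuple[float, ...] = (0.0, 0.02, 0.05, 0.1)
    scan_report_reactions: tuple[str, ...] = ("ACCOAC", "CS")
    scenario_reaction: str = "3OAS180"
    scenario_factor: float = 2.0
    conditions: Optional[dict[str, ConditionSpec]] = None

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return PipelineConfig.from_dict(doc)

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        if "fseof" in doc and isinstance(doc["fseof"], dict):
            doc["fseof"] = FSEOFConfig(**doc["fseof"])
        if "ga" in doc and isinstance(doc["ga"], dict):
            ga = dict(doc["ga"])
            # accept the common external parameter names
            renames = {"popsize": "population_size",
                       "genlimit": "generation_limit",
                       "mingrowth": "min_growth",
                       "maxreductionsize": "max_knockouts",
                       "ignorelistrxns": "ignore_reactions",
                       "biomassrxn": "biomass_reaction"}
            for old, new in renames.items():
                if old in ga:
                    ga[new] = ga.pop(old)
            if "ignore_reactions" in ga:
                ga["ignore_reactions"] = tuple(ga["ignore_reactions"])
            doc["ga"] = GAParams(**ga)
        if "conditions" in doc and isinstance(doc["conditions"], dict):
            specs = {}
            for name, spec in doc["conditions"].items():
                overrides = tuple(
                    BoundOverride(o["reaction"], float(o["lb"]),
                                  float(o["ub"]),
                                  o.get("orientation", "forward"))
                    for o in spec.get("overrides", []))
                specs[name] = ConditionSpec(
                    name=name, biomass_reaction=spec["biomass_reaction"],
                    overrides=overrides,
                    biomass_variants=tuple(spec.get("biomass_variants", ())))
            doc["conditions"] = specs
        for key in ("scan_levels", "scan_report_reactions"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return PipelineConfig(**doc)

    def config_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_tsv(path: Path, rows: Sequence[dict], columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v + 0.0:.10g}"          # normalise -0.0
    return str(v)


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


class StageError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig,
                 stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the requested stages; returns the manifest dict.

    Stage order follows dependencies (essentiality before design
    reduction).  On stage failure a partial manifest recording the failure
    is written and :class:`StageError` is raised.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in ALL_STAGES if s in set(stages)]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = read_model_json(cfg.model_path)

    manifest: dict = {"package_version": __version__,
                      "config_hash": cfg.config_hash(),
                      "seed": cfg.seed, "model_id": model.model_id,
                      "stages": {}}
    state: dict = {}

    def record(stage: str, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(exc)}
            _write_json(out / "manifest.json", manifest)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "wall_time_s": round(time.perf_counter() - t0, 3)}

    def stage_fba():
        sol = optimize(model)
        _write_json(out / "fba.json", {
            "objective": model.objective_reaction,
            "status": sol.status, "growth_rate": sol.objective_value})

    def stage_essentiality():
        growth = single_gene_deletion(model)
        predicted = classify_essential(growth, cfg.essentiality_threshold)
        state["essential_genes"] = sorted(
            g for g, lab in predicted.items() if lab == "essential")
        payload = {"threshold": cfg.essentiality_threshold,
                   "n_essential": len(state["essential_genes"])}
        if cfg.labels_path:
            if not Path(cfg.labels_path).exists():
                raise FileNotFoundError(
                    f"essentiality label table not found: {cfg.labels_path}")
            experimental = read_label_table(cfg.labels_path)
            counts = confusion(predicted, experimental)
            stats = compute_stats(counts)
            n_excluded = sum(
                1 for g in predicted
                if experimental.get(g, "untested") not in
                ("essential", "non_essential"))
            payload.update({
                "counts": {"TP": counts.TP, "TN": counts.TN,
                           "FP": counts.FP, "FN": counts.FN},
                "n_excluded": n_excluded,
                "stats": stats.rounded()})
            rows = screen_report_rows(growth, predicted, experimental)
        else:
            rows = [{"gene": g, "knockout_growth": growth[g],
                     "predicted_label": predicted[g],
                     "experimental_label": "untested", "class": "excluded"}
                    for g in sorted(growth)]
        write_tsv(out / "essentiality.tsv", rows,
                  ["gene", "knockout_growth", "predicted_label",
                   "experimental_label", "class"])
        _write_json(out / "essentiality_stats.json", payload)

    def stage_envelope():
        pts = production_envelope(model, cfg.target, cfg.envelope_points)
        write_tsv(out / "envelope.tsv",
                  [{"growth": p.growth, "min": p.min_production,
                    "max": p.max_production} for p in pts],
                  ["growth", "min", "max"])

    def stage_fseof():
        res = fseof(model, cfg.target, cfg.fseof)
        rows = []
        for r in sorted(res.profiles):
            row = {"reaction": r,
                   "subsystem": model.reaction(r).subsystem,
                   "class": res.classification[r]}
            for i, v in enumerate(res.profiles[r], 1):
                row[f"flux_step_{i}"] = v
            rows.append(row)
        cols = ["reaction", "subsystem"] + \
            [f"flux_step_{i}" for i in range(1, len(res.steps) + 1)] + ["class"]
        write_tsv(out / "fseof.tsv", rows, cols)
        _write_json(out / "fseof_targets.json",
                    {"target": cfg.target, "n_targets": len(res.targets),
                     "targets": res.targets,
                     "anti_targets": res.anti_targets})

    def _candidates():
        if "essential_genes" not in state:
            growth = single_gene_deletion(model)
            predicted = classify_essential(growth,
                                           cfg.essentiality_threshold)
            state["essential_genes"] = sorted(
                g for g, lab in predicted.items() if lab == "essential")
        if "candidates" not in state:
            state["candidates"] = reduce_for_design(
                model, state["essential_genes"],
                cfg.blocked_biomass_fraction)
        return state["candidates"]

    def stage_design():
        ranked, meta = enumerate_knockouts(
            model, cfg.target, cfg.design_k_max, _candidates(),
            min_growth=cfg.ga.min_growth)
        rows = [{"knockouts": ";".join(sorted(c.knockouts)),
                 "max_growth": c.max_growth,
                 "coupling_strength": c.product_at_max_growth,
                 "max_product": c.max_product} for c in ranked]
        write_tsv(out / "design.tsv", rows,
                  ["knockouts", "max_growth", "max_product",
                   "coupling_strength"])
        _write_json(out / "design_meta.json", meta)

    def stage_ga():
        params = cfg.ga
        if not params.biomass_reaction:
            params = GAParams(**{**asdict(params),
                                 "biomass_reaction": model.objective_reaction,
                                 "seed": cfg.seed})
        front = ga_coupling_search(model, cfg.target, params,
                                   candidates=_candidates())
        rows = [{"knockouts": ";".join(sorted(c.knockouts)),
                 "max_growth": c.max_growth,
                 "coupling_strength": c.product_at_max_growth,
                 "max_product": c.max_product} for c in front]
        write_tsv(out / "ga_front.tsv", rows,
                  ["knockouts", "max_growth", "max_product",
                   "coupling_strength"])

    def stage_sample():
        control = sample_fluxes(model, cfg.sample_n, cfg.seed)
        scen = RegulationScenario(cfg.scenario_reaction, cfg.scenario_factor)
        scenario_model = apply_scenario(model, scen)
        scenario = sample_fluxes(scenario_model, cfg.sample_n, cfg.seed + 1)
        summary = compare_distributions(control, scenario)
        rows = [{"reaction": r, **summary[r]} for r in sorted(summary)]
        write_tsv(out / "sampling_shifts.tsv", rows,
                  ["reaction", "mean_a", "mean_b", "q05_a", "q95_a",
                   "q05_b", "q95_b", "pooled_se", "shift"])
        _write_json(out / "sampling_meta.json", {
            "n": cfg.sample_n, "seed": cfg.seed,
            "warmup": control.n_warmup, "thinning": control.thinning,
            "scenario": {"reaction": cfg.scenario_reaction,
                         "factor": cfg.scenario_factor}})

    def _condition_models():
        if "condition_models" not in state:
            specs = cfg.conditions or miniphoto_condition_specs()
            state["condition_models"] = {
                name: apply_condition(model, spec)
                for name, spec in specs.items()}
        return state["condition_models"]

    def stage_conditions():
        cms = _condition_models()
        comp = compare_envelopes(cms, cfg.target, cfg.envelope_points)
        rows = []
        for name, entry in comp.items():
            for p in entry["envelope"]:
                rows.append({"condition": name, "growth": p.growth,
                             "min": p.min_production,
                             "max": p.max_production})
        write_tsv(out / "condition_envelopes.tsv", rows,
                  ["condition", "growth", "min", "max"])
        summary = {name: {"mu_max": entry["mu_max"],
                          "max_product": entry["max_product"]}
                   for name, entry in comp.items()}
        activity_rxns = [r for r in ("PSIIum", "PSIum", "EX_o2", "EX_photon")
                         if r in set(model.reaction_ids)]
        if activity_rxns and "photoautotrophy" in cms:
            act = photosynthetic_activity(cms, activity_rxns)
            summary["activity_ratios"] = act.ratios
        _write_json(out / "conditions.json", summary)

    def stage_scan():
        cms = _condition_models()
        rows = []
        for name, cm in cms.items():
            for row in overexpression_scan(cm, cfg.scan_reaction,
                                           cfg.scan_levels, cfg.target,
                                           cfg.scan_report_reactions):
                rows.append({"condition": name, **row})
        cols = ["condition", "level", "feasible", "mu_max",
                "target_at_mu_max", *cfg.scan_report_reactions]
        write_tsv(out / "overexpression_scan.tsv", rows, cols)

    runners = {"fba": stage_fba, "essentiality": stage_essentiality,
               "envelope": stage_envelope, "fseof": stage_fseof,
               "design": stage_design, "ga": stage_ga,
               "sample": stage_sample, "conditions": stage_conditions,
               "scan": stage_scan}
    for stage in stages:
        record(stage, runners[stage])
    _write_json(out / "manifest.json", manifest)
    return manifest
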