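"""Synthetic phototroph models and simulated essentiality ground truth.

The flagship generator, :func:`make_toy_phototroph`, builds *MiniPhoto*: a
~35-reaction, ~28-metabolite cyanobacterium-like network with

* lumped photosystem II / photosystem I reactions producing ATP and NADPH
  from photons and evolving O2, plus cyclic photophosphorylation;
* a RuBisCO-like carboxylation fixing CO2 into a generic fixed-carbon unit;
* an acetyl-CoA node fed by pyruvate dehydrogenase and, optionally, by
  acetate activation and lumped glucose catabolism;
* a saturated fatty-acid chain (acetyl-CoA carboxylase -> FabH-like
  initiation -> FabF-like lumped elongation to C18:0) followed by the
  desaturase cascade C18:0 -> C18:1 -> C18:2 -> alpha-linolenic acid (ALA)
  with a demand reaction DM_ALA;
* competing amino-acid and respiration sinks on pyruvate/acetyl-CoA;
* three biomass variants (photoautotrophy, acetate and glucose
  photomixotrophy) consuming C18:0 and amino-acid units plus ATP — none of
  them consumes ALA, so ALA production is *not* growth-coupled.

Two deliberate structural choices drive the regulation-scenario behaviour:

* the membrane-incorporation sink sits on the C18:1 pool, *downstream* of
  the stearoyl desaturase but *upstream* of the Delta-12 desaturase.
  Forcing elongation flux therefore forces the stearoyl-desaturase flux
  (the surplus C18:0 has nowhere else to go) without forcing the later
  desaturases, mirroring the observed asymmetry between FabF and FabH
  manipulations;
* respiration returns both ATP and reduced cofactor from acetyl-CoA, a
  maintenance reaction absorbs surplus ATP, and the acetate-fed route from
  acetyl-CoA to ALA consumes ATP and NADPH in exactly the 1:1 ratio that
  respiration supplies.  Acetate-fed metabolism can therefore pay for extra
  desaturase flux without drawing on the photon budget (the Delta-12
  overexpression scan leaves growth untouched under acetate), while the
  same route is exactly energy-neutral as a cofactor dump, so it is never
  *forced* at maximal growth and ALA stays non-growth-coupled;
* chain initiation is redundant: a house acetyl-CoA:ACP transacylase route
  and an ATP-costlier KAS III variant share the FabH-like gene (knocking
  the gene removes both, so it stays essential), and a short-chain
  acyl-ACP release valve sits between initiation and elongation.  Forcing
  flux through the KAS III reaction is therefore absorbed upstream of the
  elongation step and does not propagate to the desaturases;
* nitrogen assimilation (nitrate reduction) consumes reduced ferredoxin
  directly, as it does in vivo.  Ferredoxin comes only from photosystem I,
  so amino-acid (and hence biomass) synthesis is photon-obligate under
  every regimen: organic carbon enlarges the solution space without making
  light dispensable, and photon uptake stays saturated at maximal growth.

All stoichiometric coefficients are small integers so that hand/oracle
checks stay exact; they are a test contract of this package, not measured
values.  Every metabolite carries a carbon-unit annotation and every
internal reaction is carbon-balanced (self-checked at generation time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .essentiality import classify_essential, single_gene_deletion
from .model import (MetabolicModel, Metabolite, Reaction, carbon_imbalances,
                    parse_gpr)


@dataclass(frozen=True)
class ToyConfig:
    photon_budget: float = 100.0        # mmol photons gDW^-1 h^-1
    include_acetate: bool = True
    include_glucose: bool = True
    fatty_acid_coeff: float = 0.25      # C18:0 units per biomass unit
    amino_acid_coeff: float = 3.0       # amino-acid units per biomass unit
    # glucose-grown cells carry a lower protein fraction (condition-specific
    # biomass composition), modelled as a smaller amino-acid coefficient
    amino_acid_coeff_glucose: float = 2.0
    n_extra_genes: int = 0              # gene inflation for screen statistics
    seed: int = 0

    def __post_init__(self):
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.fatty_acid_coeff <= 0 or self.amino_acid_coeff <= 0:
            raise ValueError("biomass coefficients must be positive")


@dataclass(frozen=True)
class LabelNoiseConfig:
    flip_rate: float = 0.1
    n_ambiguous: int = 0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")
        if self.n_ambiguous < 0:
            raise ValueError("n_ambiguous must be non-negative")


BIOMASS_VARIANTS = {
    "photoautotrophy": "BOF_photoautotrophy",
    "acetate_photomixotrophy": "BOF_acetate_photomixotrophy",
    "glucose_photomixotrophy": "BOF_glucose_photomixotrophy",
}


def make_toy_phototroph(cfg: ToyConfig = ToyConfig()) -> MetabolicModel:
    """Build the MiniPhoto model.  Deterministic: equal configs give
    structurally identical models."""
    fa = cfg.fatty_acid_coeff
    aa = cfg.amino_acid_coeff
    aa_glc = cfg.amino_acid_coeff_glucose
    bm_carbon = 18.0 * fa + 3.0 * aa
    bm_carbon_glc = 18.0 * fa + 3.0 * aa_glc

    mets = [
        # extracellular
        Metabolite("photon_e", "photon", "e", carbon=0),
        Metabolite("co2_e", "CO2", "e", formula="CO2", carbon=1),
        Metabolite("o2_e", "O2", "e", formula="O2", carbon=0),
        Metabolite("ac_e", "acetate", "e", carbon=2),
        Metabolite("glc_e", "glucose", "e", carbon=6),
        Metabolite("no3_e", "nitrate", "e", carbon=0),
        # cytosolic
        Metabolite("photon_c", "photon", "c", carbon=0),
        Metabolite("co2_c", "CO2", "c", formula="CO2", carbon=1),
        Metabolite("o2_c", "O2", "c", formula="O2", carbon=0),
        Metabolite("ac_c", "acetate", "c", carbon=2),
        Metabolite("glc_c", "glucose", "c", carbon=6),
        Metabolite("no3_c", "nitrate", "c", carbon=0),
        Metabolite("nh4_c", "ammonium", "c", carbon=0),
        Metabolite("pq_c", "plastoquinone (oxidised)", "c", carbon=0),
        Metabolite("pqh2_c", "plastoquinol (reduced)", "c", carbon=0),
        Metabolite("fdx_c", "reduced ferredoxin (2 e-)", "c", carbon=0),
        Metabolite("atp_c", "ATP (energy unit)", "c", carbon=0),
        Metabolite("nadph_c", "NADPH (reductant unit)", "c", carbon=0),
        Metabolite("ch2o_c", "fixed-carbon unit", "c", carbon=1),
        Metabolite("pyr_c", "pyruvate", "c", carbon=3),
        Metabolite("accoa_c", "acetyl-CoA (C2 unit)", "c", carbon=2),
        Metabolite("maloa_c", "malonyl-ACP (C3 unit)", "c", carbon=3),
        Metabolite("acp4_c", "butyryl-ACP (C4)", "c", carbon=4),
        Metabolite("fa180_c", "stearoyl-ACP (C18:0)", "c", carbon=18),
        Metabolite("fa181_c", "oleoyl lipid (C18:1)", "c", carbon=18),
        Metabolite("fa182_c", "linoleoyl lipid (C18:2)", "c", carbon=18),
        Metabolite("ala_c", "alpha-linolenoyl lipid (C18:3, ALA)", "c", carbon=18),
        Metabolite("aa_c", "amino-acid unit", "c", carbon=3),
        Metabolite("bm_photo_c", "biomass (photoautotrophic)", "c", carbon=bm_carbon),
        Metabolite("bm_ac_c", "biomass (acetate)", "c", carbon=bm_carbon),
        Metabolite("bm_glc_c", "biomass (glucose)", "c", carbon=bm_carbon_glc),
    ]

    def rxn(rid, name, stoich, lb, ub, gpr="", subsystem=""):
        return Reaction(rid, name, stoich, lb, ub, parse_gpr(gpr), subsystem)

    rxns = [
        # --- boundary ---------------------------------------------------
        rxn("EX_photon", "photon exchange", {"photon_e": -1}, -cfg.photon_budget, 0.0,
            subsystem="Exchange"),
        rxn("EX_co2", "CO2 exchange", {"co2_e": -1}, -1000, 1000, subsystem="Exchange"),
        rxn("EX_o2", "O2 exchange", {"o2_e": -1}, -1000, 1000, subsystem="Exchange"),
        rxn("EX_ac", "acetate exchange", {"ac_e": -1}, 0, 1000, subsystem="Exchange"),
        rxn("EX_glc", "glucose exchange", {"glc_e": -1}, 0, 1000, subsystem="Exchange"),
        rxn("EX_no3", "nitrate exchange", {"no3_e": -1}, -1000, 0, subsystem="Exchange"),
        rxn("DM_ALA", "ALA demand", {"ala_c": -1}, 0, 1000, subsystem="Demand"),
        rxn("SK_fa181", "C18:1 membrane incorporation", {"fa181_c": -1}, 0, 1000,
            subsystem="Demand"),
        rxn("SK_c4", "short-chain acyl-ACP release (thioesterase)",
            {"acp4_c": -1}, 0, 1000, subsystem="Demand"),
        rxn("DM_biomass_photo", "biomass drain (photo)", {"bm_photo_c": -1}, 0, 1000,
            subsystem="Demand"),
        rxn("DM_biomass_ac", "biomass drain (acetate)", {"bm_ac_c": -1}, 0, 1000,
            subsystem="Demand"),
        rxn("DM_biomass_glc", "biomass drain (glucose)", {"bm_glc_c": -1}, 0, 1000,
            subsystem="Demand"),
        # --- transport --------------------------------------------------
        rxn("PHOt", "photon capture", {"photon_e": -1, "photon_c": 1}, 0, 1000,
            "gPHOt", "Transport: Thylakoid"),
        rxn("CO2t", "CO2 diffusion/uptake", {"co2_e": -1, "co2_c": 1}, -1000, 1000,
            "gCO2t", "Transport: Inner Membrane"),
        rxn("O2t", "O2 diffusion", {"o2_c": -1, "o2_e": 1}, -1000, 1000,
            "gO2t", "Transport: Inner Membrane"),
        rxn("ACtex", "acetate uptake", {"ac_e": -1, "ac_c": 1}, 0, 1000,
            "gACt", "Transport: Inner Membrane"),
        rxn("GLCtex", "glucose uptake", {"glc_e": -1, "glc_c": 1}, 0, 1000,
            "gGLCt", "Transport: Inner Membrane"),
        rxn("NO3t", "nitrate uptake", {"no3_e": -1, "no3_c": 1}, 0, 1000,
            "gNO3t", "Transport: Inner Membrane"),
        # --- photosynthesis ---------------------------------------------
        rxn("PSIIum", "photosystem II (lumped)",
            {"photon_c": -4, "pq_c": -2, "pqh2_c": 2, "o2_c": 1}, 0, 1000,
            "gPSIIa and gPSIIb", "Photosynthesis"),
        rxn("PSIum", "photosystem I + b6f (lumped)",
            {"photon_c": -2, "pqh2_c": -1, "pq_c": 1, "fdx_c": 1, "atp_c": 1},
            0, 1000, "gPSIa and gPSIb", "Photosynthesis"),
        rxn("FNR", "ferredoxin-NADP+ reductase", {"fdx_c": -1, "nadph_c": 1},
            0, 1000, "gFNR", "Photosynthesis"),
        rxn("CEF", "cyclic photophosphorylation (lumped)",
            {"photon_c": -2, "atp_c": 1}, 0, 1000, "gCEF", "Photosynthesis"),
        # --- carbon fixation --------------------------------------------
        rxn("RBPCcx", "RuBisCO carboxylation (lumped CBB)",
            {"co2_c": -1, "atp_c": -3, "nadph_c": -2, "ch2o_c": 1}, 0, 1000,
            "gRBCL and gRBCS", "Calvin cycle"),
        # --- central metabolism -----------------------------------------
        rxn("PYRS", "lower glycolysis (fixed carbon to pyruvate)",
            {"ch2o_c": -3, "atp_c": -1, "pyr_c": 1}, 0, 1000,
            "gPYRS", "Central metabolism"),
        rxn("PDH", "pyruvate dehydrogenase",
            {"pyr_c": -1, "accoa_c": 1, "co2_c": 1, "nadph_c": 1}, 0, 1000,
            "gPDH1 or gPDH2", "Central metabolism"),
        rxn("ACS", "acetyl-CoA synthetase",
            {"ac_c": -1, "atp_c": -1, "accoa_c": 1}, 0, 1000,
            "gACS", "Pyruvate metabolism"),
        rxn("GLK", "glucose catabolism (lumped glycolysis)",
            {"glc_c": -1, "pyr_c": 2, "atp_c": 2, "nadph_c": 2}, 0, 1000,
            "gGLK", "Central metabolism"),
        rxn("CS", "respiration (lumped TCA + oxidative phosphorylation)",
            {"accoa_c": -1, "o2_c": -2, "co2_c": 2, "atp_c": 2, "nadph_c": 1},
            0, 1000, "gCS", "TCA cycle"),
        rxn("NAR", "nitrate reduction to ammonium (ferredoxin-dependent)",
            {"no3_c": -1, "fdx_c": -4, "nh4_c": 1}, 0, 1000,
            "gNAR", "Nitrogen metabolism"),
        rxn("AAS", "amino-acid synthesis (lumped)",
            {"pyr_c": -1, "atp_c": -1, "nh4_c": -1, "aa_c": 1}, 0, 1000,
            "gAAS1 or gAAS2", "Amino acid metabolism"),
        rxn("ATPM", "ATP maintenance", {"atp_c": -1}, 0, 1000,
            subsystem="Maintenance"),
        # --- fatty-acid biosynthesis ------------------------------------
        rxn("ACCOAC", "acetyl-CoA carboxylase",
            {"accoa_c": -1, "co2_c": -1, "atp_c": -1, "maloa_c": 1}, 0, 1000,
            "gACCa and gACCd", "Fatty acid biosynthesis"),
        rxn("KAS15", "beta-ketoacyl-ACP synthase III (FabH-like initiation)",
            {"accoa_c": -1, "maloa_c": -1, "nadph_c": -2, "atp_c": -1,
             "acp4_c": 1, "co2_c": 1}, 0, 1000,
            "gKASH", "Fatty acid biosynthesis"),
        rxn("ACOATA", "acetyl-CoA:ACP transacylase initiation (FabD-dependent)",
            {"accoa_c": -1, "maloa_c": -1, "nadph_c": -2,
             "acp4_c": 1, "co2_c": 1}, 0, 1000,
            "gKASH and gFABD", "Fatty acid biosynthesis"),
        rxn("3OAS180", "beta-ketoacyl-ACP synthase I (FabF-like lumped elongation)",
            {"acp4_c": -1, "maloa_c": -7, "nadph_c": -12,
             "fa180_c": 1, "co2_c": 7}, 0, 1000,
            "gKASF", "Fatty acid biosynthesis"),
        rxn("DESAT18a", "stearoyl desaturase (DesC-like, C18:0 -> C18:1)",
            {"fa180_c": -1, "o2_c": -1, "nadph_c": -1, "fa181_c": 1}, 0, 1000,
            "gDESC", "Fatty acid biosynthesis"),
        rxn("DES12", "Delta-12 desaturase (DesA-like, C18:1 -> C18:2)",
            {"fa181_c": -1, "o2_c": -1, "nadph_c": -1, "fa182_c": 1}, 0, 1000,
            "gDESA", "Fatty acid biosynthesis"),
        rxn("DES15", "Delta-15 desaturase (DesB-like, C18:2 -> ALA)",
            {"fa182_c": -1, "o2_c": -1, "nadph_c": -1, "ala_c": 1}, 0, 1000,
            "gDESB", "Fatty acid biosynthesis"),
        # --- biomass variants -------------------------------------------
        rxn("BOF_photoautotrophy", "biomass, photoautotrophic",
            {"aa_c": -aa, "fa180_c": -fa, "atp_c": -30, "bm_photo_c": 1},
            0, 1000, subsystem="Biomass"),
        rxn("BOF_acetate_photomixotrophy", "biomass, acetate photomixotrophy",
            {"aa_c": -aa, "fa180_c": -fa, "atp_c": -32, "bm_ac_c": 1},
            0, 0, subsystem="Biomass"),
        rxn("BOF_glucose_photomixotrophy", "biomass, glucose photomixotrophy",
            {"aa_c": -aa_glc, "fa180_c": -fa, "atp_c": -33, "bm_glc_c": 1},
            0, 0, subsystem="Biomass"),
    ]

    genes = {
        "gPHOt": "photon antenna", "gCO2t": "carbon uptake", "gO2t": "O2 diffusion",
        "gACt": "acetate permease", "gGLCt": "glucose permease",
        "gNO3t": "nitrate transporter", "gNAR": "nitrate/nitrite reductase",
        "gPSIIa": "PSII core D1", "gPSIIb": "PSII core D2",
        "gPSIa": "PSI core A", "gPSIb": "PSI core B",
        "gFNR": "ferredoxin-NADP+ reductase", "gCEF": "cyclic electron flow",
        "gRBCL": "RuBisCO large subunit", "gRBCS": "RuBisCO small subunit",
        "gPYRS": "lower glycolysis", "gPDH1": "PDH E1 isozyme 1",
        "gPDH2": "PDH E1 isozyme 2", "gACS": "acetyl-CoA synthetase",
        "gGLK": "glucokinase/glycolysis", "gCS": "citrate synthase (respiration)",
        "gAAS1": "amino-acid synthesis isozyme 1",
        "gAAS2": "amino-acid synthesis isozyme 2",
        "gACCa": "acetyl-CoA carboxylase, carboxyltransferase",
        "gACCd": "acetyl-CoA carboxylase, biotin carboxylase",
        "gKASH": "FabH-like KAS III", "gKASF": "FabF-like KAS I/II",
        "gFABD": "malonyl-CoA:ACP transacylase",
        "gDESC": "DesC-like Delta-9 desaturase",
        "gDESA": "DesA-like Delta-12 desaturase",
        "gDESB": "DesB-like Delta-15 desaturase",
    }

    if not cfg.include_acetate:
        rxns = [r for r in rxns if r.id not in ("EX_ac", "ACtex", "ACS")]
        mets = [m for m in mets if m.id not in ("ac_e", "ac_c")]
        for g in ("gACt", "gACS"):
            genes.pop(g)
    if not cfg.include_glucose:
        rxns = [r for r in rxns if r.id not in ("EX_glc", "GLCtex", "GLK")]
        mets = [m for m in mets if m.id not in ("glc_e", "glc_c")]
        for g in ("gGLCt", "gGLK"):
            genes.pop(g)

    # Optional gene inflation for screen-statistics studies: extra genes are
    # attached alternately as OR-isozymes of the amino-acid synthesis step
    # (individually dispensable) and as AND-members of the carboxylation
    # complex (individually indispensable).
    if cfg.n_extra_genes:
        width = len(str(cfg.n_extra_genes))
        extra = [f"gX{i:0{width}d}" for i in range(cfg.n_extra_genes)]
        for g in extra:
            genes[g] = "simulated gene"
        odd = [g for i, g in enumerate(extra) if i % 2]
        even = [g for i, g in enumerate(extra) if not i % 2]
        by_id = {r.id: r for r in rxns}

        def amend(rid, new_gpr):
            old = by_id[rid]
            idx = rxns.index(old)
            rxns[idx] = Reaction(old.id, old.name, old.stoichiometry,
                                 old.lower_bound, old.upper_bound,
                                 parse_gpr(new_gpr), old.subsystem)

        if even:
            amend("AAS", " or ".join(["gAAS1", "gAAS2"] + even))
        if odd:
            amend("RBPCcx", " and ".join(["gRBCL", "gRBCS"] + odd))

    model = MetabolicModel(
        model_id="MiniPhoto", metabolites=mets, reactions=rxns,
        genes=genes, objective_reaction="BOF_photoautotrophy")

    bad = carbon_imbalances(model)
    if bad:  # pragma: no cover - generator self-check
        raise AssertionError(f"carbon imbalance in generated model: {bad}")
    return model


def make_essentiality_truth(model: MetabolicModel, noise: LabelNoiseConfig,
                            true_labels: dict[str, str] | None = None
                            ) -> dict[str, str]:
    """Simulated experimental essentiality labels.

    True labels come from the in-silico single-gene screen (or are supplied);
    each is flipped with probability ``flip_rate`` and ``n_ambiguous``
    randomly chosen genes are then marked ambiguous.  Seeded and
    reproducible.
    """
    if len(model.genes) < 10:
        raise ValueError("model must have at least 10 genes")
    if true_labels is None:
        growth = single_gene_deletion(model)
        true_labels = classify_essential(growth)
    rng = np.random.default_rng(noise.seed)
    genes = sorted(true_labels)
    flip = rng.random(len(genes)) < noise.flip_rate
    out = {}
    for g, f in zip(genes, flip):
        lab = true_labels[g]
        if f:
            lab = "non_essential" if lab == "essential" else "essential"
        out[g] = lab
    if noise.n_ambiguous:
        for g in rng.choice(genes, size=noise.n_ambiguous, replace=False):
            out[g] = "ambiguous"
    return out


# ---------------------------------------------------------------------------
# Desk-scale fixtures: hand-solvable LPs
# ---------------------------------------------------------------------------

def make_chain_toy() -> MetabolicModel:
    """Three-reaction chain: EX_A(-10,0) -> A -> B -> biomass; mu_max = 10."""
    mets = [Metabolite("a", "A", "c", carbon=1),
            Metabolite("b", "B", "c", carbon=1)]
    rxns = [
        Reaction("EX_A", "A exchange", {"a": -1}, -10, 0),
        Reaction("R_AB", "A to B", {"a": -1, "b": 1}, 0, 1000,
                 parse_gpr("g1")),
        Reaction("BIOMASS", "biomass", {"b": -1}, 0, 1000),
    ]
    return MetabolicModel("chain", mets, rxns, {"g1": "converter"}, "BIOMASS")


def make_two_sink_toy(overflow_lb: float = 0.0) -> MetabolicModel:
    """Precursor P (input 10) split between biomass and a product sink.

    Envelope: max product at growth g equals 10 - g - overflow_lb.  With
    ``overflow_lb > 0`` a wasteful forced drain competes for P; knocking it
    out recovers the full trade-off.
    """
    mets = [Metabolite("p", "precursor", "c", carbon=1)]
    rxns = [
        Reaction("EX_P", "P exchange", {"p": -1}, -10, 0),
        Reaction("BIOMASS", "biomass sink", {"p": -1}, 0, 1000),
        Reaction("DM_PROD", "product sink", {"p": -1}, 0, 1000,
                 parse_gpr("gP")),
    ]
    genes = {"gP": "product branch"}
    if overflow_lb > 0:
        rxns.append(Reaction("OVERFLOW", "wasteful overflow", {"p": -1},
                             overflow_lb, 1000, parse_gpr("gOV")))
        genes["gOV"] = "overflow branch"
    return MetabolicModel("two_sink", mets, rxns, genes, "BIOMASS")


def make_byproduct_toy(yield_coeff: float = 0.5) -> MetabolicModel:
    """Biomass stoichiometrically co-produces the product: growth-coupled.

    coupling_strength(DM_Q) = yield_coeff * mu_max by construction.
    """
    mets = [Metabolite("p", "precursor", "c", carbon=1),
            Metabolite("q", "byproduct", "c", carbon=0)]
    rxns = [
        Reaction("EX_P", "P exchange", {"p": -1}, -10, 0),
        Reaction("BIOMASS", "biomass with byproduct",
                 {"p": -1, "q": yield_coeff}, 0, 1000),
        Reaction("DM_Q", "byproduct sink", {"q": -1}, 0, 1000,
                 parse_gpr("gQ")),
    ]
    return MetabolicModel("byproduct", mets, rxns, {"gQ": "drain"}, "BIOMASS")


def make_interval_toy(width: float = 10.0) -> MetabolicModel:
    """A single free flux on [0, width]: the steady-state polytope is the
    1-D segment v1 = v2 in [0, width] (uniform-sampling oracle)."""
    mets = [Metabolite("a", "A", "c", carbon=1)]
    rxns = [
        Reaction("R_IN", "source", {"a": 1}, 0, width),
        Reaction("R_OUT", "sink", {"a": -1}, 0, 1000),
    ]
    return MetabolicModel("interval", mets, rxns, {}, "R_OUT")
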