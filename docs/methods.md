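# Methods

## The constraint-based model

All analyses operate on a genome-scale metabolic model: a stoichiometric
matrix `S` (metabolites × reactions), flux bounds `lb ≤ v ≤ ub` (mmol
gDW⁻¹ h⁻¹; the biomass pseudo-reaction in h⁻¹), boolean
gene–protein–reaction (GPR) rules, and one objective reaction (the biomass
objective function, BOF). Flux balance analysis (FBA) solves

    max c·v   s.t.   S·v = 0,   lb ≤ v ≤ ub

with HiGHS through `scipy.optimize.linprog`. Steady state (`S·v = 0`)
assumes no net metabolite accumulation; the optimal BOF flux is the
predicted growth rate.

Two numerical tolerances matter: primal feasibility (default 1e-9,
applied to `|S·v|` and bound violations when verifying solutions) and
optimality (default 1e-6, the resolution at which two objective values
are considered equal and the back-off used when a solved optimum is
re-imposed as a constraint). LP vertices are degenerate in metabolic
models, so no pipeline quantity is defined through a single optimal flux
vector: essentiality uses objective values, envelopes and FSEOF use flux
variability analysis (FVA) ranges, and scans report FVA-interval
midpoints. μ_max is recomputed on every call and never cached across
model mutations.

## Gene essentiality

A single-gene deletion closes (bounds to 0, never deletes) every reaction
whose GPR evaluates false with that gene removed; orphan reactions (empty
GPR) are untouched. A gene is called essential when the mutant's maximal
growth falls strictly below 1e-3 h⁻¹, read as an absolute rate; a
relative-to-wild-type mode exists for robustness studies. Predictions are
scored against experimental labels after excluding genes labelled
ambiguous or untested and genes absent from either table:

- accuracy = (TP+TN)/N · 100, sensitivity = TP/(TP+FN) · 100,
  specificity = TN/(TN+FP) · 100, precision = TP/(TP+FP) · 100
- F1 = 2TP/(2TP+FP+FN)
- Cohen's κ = 2(TP·TN − FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN))

Counts are kept in exact rational arithmetic until the final float
conversion; percentages are reported to one decimal. Zero denominators
yield an explicit "undefined", never 0. Note the convention: FN counts
experimentally essential genes predicted non-essential (it enters
sensitivity), FP the converse (it enters specificity) — screens described
loosely in prose are pinned down by which reported statistic moves.

## Strain design

**FSEOF** (flux scanning based on enforced objective flux): growth is
held at ≥ 80% of μ_max, the product's maximum is computed *under that
constraint* (this guarantees every enforcement step is feasible; computing
it unconstrained can make the default settings infeasible on strongly
photon-limited models where product and growth compete linearly for the
same budget), and the product's lower bound is raised in 10 uniform steps
to 80% of that maximum. Per-step, per-reaction fluxes are FVA midpoints.
Classification: monotone increase of |flux| with constant sign and total
change ≥ 1e-6 → over-expression target; monotone decrease → anti-target;
anything else unaffected.

**Reduction and knockout search.** Candidate deletions are non-blocked
reactions (FVA at 20% of μ_max), with a known GPR containing no essential
gene, excluding transport/boundary reactions and the BOF. Designs of size
≤ k are enumerated exhaustively when the subset count fits a budget
(default 20 000 evaluations), else by deterministic greedy beam search;
this replaces bilevel MILP formulations, whose outcomes it reproduces on
desk-scale instances while remaining solver-agnostic. A design is scored
by (max growth, max product at the viability floor, coupling strength),
where **coupling strength** = minimum product flux with growth fixed at
μ_max; positive coupling means the product is obligatory at optimal
growth. Ranking is lexicographic: coupling desc, product desc, fewer
knockouts, then ids.

**GA coupling search.** A seeded genetic algorithm over knockout
bit-vectors: tournament selection of size 2, uniform crossover p = 0.5,
per-bit mutation 1/n, random repair to the knockout cap, fitness =
(growth, product, coupling) with Pareto non-domination; sub-viability
individuals rank below all feasible ones. The returned front is the
non-dominated set over every design evaluated, so it can only improve on
the population. Full-scale settings (population 1000, generation limit
100 000, up to 30 knockouts) are configuration defaults; the test suite
and acceptance script run population 24–40 for 12–25 generations on the
six-candidate toy pool, where the GA front is verified against exhaustive
enumeration.

## Flux sampling

Artificial-centering hit-and-run: warmup points are optimal vertices of
randomized-objective LPs (axis-aligned objectives first, then Gaussian),
the chain moves along directions from the running center towards random
warmup points, with the step uniform on the feasible chord. Directions
are differences of feasible points, so iterates remain on `S·v = 0`;
round-off is removed every 200 iterations by orthogonal projection onto
the null space. Defaults: warmup = 2 × reactions (cap 500), thinning 10,
seed mandatory. Every emitted sample is checked against steady state and
bounds at 1e-6.

Regulation scenarios scale a reaction against a **reference flux**, the
control model's FVA midpoint at 99% of μ_max — a degeneracy-robust stand-in
for "the flux the wild type carries". Over-expression (factor ≥ 1) raises
the lower bound; down-regulation lowers the upper bound, mirroring the
asymmetry of the biological interventions. Distribution comparisons report
per-reaction means, 5–95% quantiles and a shift direction, called only
when |Δmean| exceeds twice the pooled standard error; no further
distributional testing is attempted.

## Condition-specific models

A condition spec lists absolute bound overrides with an explicit uptake
orientation per reaction: published bound tables print uptake magnitudes
as positive pairs, while exchange fluxes here are negative for uptake, so
a pair (L, U) under `uptake_negative` becomes (−U, −L). Transporters
written in their uptake direction take the pair directly. Applying a spec
also closes the non-selected biomass variants and switches the objective;
condition-specific biomass compositions are model data, not derived by
this package. The photosynthetic-activity report normalises FVA-midpoint
fluxes at μ_max to the photoautotrophic baseline, flagging zero baselines
as undefined. The forced-overexpression scan raises a reaction's lower
bound over a level grid and reports μ_max, product at μ_max and companion
fluxes per level, recording infeasible levels in-table.

## The synthetic phototroph (MiniPhoto)

A 41-reaction, 31-metabolite, 31-gene cyanobacterium-like network used by
every test and by the acceptance script. Design goals, in order: every
qualitative conclusion the pipeline is meant to surface must hold *by
construction*, coefficients must be small and hand-checkable, and each
internal reaction must balance an integer carbon annotation (self-checked
at generation time).

Structure: photon capture feeds lumped photosystem II (4 photons + 2 PQ →
2 PQH₂ + O₂) and photosystem I/b6f (2 photons + PQH₂ → PQ + Fdx + ATP),
ferredoxin-NADP⁺ reductase, and cyclic photophosphorylation (2 photons →
ATP). RuBisCO-like carboxylation fixes CO₂ (1 CO₂ + 3 ATP + 2 NADPH → CH₂O);
lower glycolysis makes pyruvate; pyruvate dehydrogenase, acetate
activation and lumped glucose catabolism feed the acetyl-CoA node;
respiration returns 2 ATP + 1 NADPH per acetyl-CoA; a maintenance
reaction absorbs surplus ATP. The fatty-acid route is acetyl-CoA
carboxylase → initiation (two routes, below) → FabF-like lumped
elongation to C18:0 → Δ9, Δ12, Δ15 desaturases (each 1 NADPH + 1 O₂) →
α-linolenic acid (ALA) with a demand reaction. Nitrogen enters as
nitrate, reduced with 4 reduced-ferredoxin equivalents per ammonium.
Three biomass variants (photoautotrophy/acetate/glucose) consume
amino-acid units, C18:0 and ATP — never ALA.

Five structural choices carry the scientific behaviour:

1. **ALA is absent from biomass**, so its production is never
   growth-coupled, under any condition or knockout of the reduced
   candidate set (verified exhaustively in the tests).
2. **Nitrogen assimilation consumes reduced ferredoxin directly**, which
   only photosystem I produces. Growth is therefore photon-obligate under
   every regimen: organic carbon raises μ_max (acetate ≈ 2.2×, glucose
   ≈ 2.9× in the shipped configuration) without making light
   dispensable, and photon uptake stays saturated at μ_max — the
   photomixotrophic photon-uptake ratio to the photoautotrophic baseline
   is 1. (The increase in photosystem flux seen in real condition-specific
   models is *not* reproduced; the toy's PSII flux ratio is below 1
   because its lumped cyclic photophosphorylation bypasses PSII.)
3. **The acetate-fed route from acetyl-CoA to ALA consumes ATP and NADPH
   at exactly the 1:1 ratio respiration supplies** (17 ATP : 17 NADPH per
   ALA, with surplus ATP absorbed by maintenance). Forcing Δ12-desaturase
   flux under acetate is therefore paid entirely by extra acetate uptake —
   growth is exactly unchanged — while under photoautotrophy the same
   forcing drains the photon budget and growth falls monotonically
   (≈ 32% at the top of the default level grid). The same parity makes
   the route energy-neutral as a cofactor dump, so it is never forced at
   μ_max and coupling stays zero. Glucose behaves like acetate here;
   the growth penalty real models show under glucose is not reproduced.
4. **Chain initiation is redundant** — a house acetyl-CoA:ACP
   transacylase route and an ATP-costlier KAS III variant share the
   FabH-like gene (so the gene stays essential), and a short-chain
   acyl-ACP release valve sits between initiation and elongation. Forcing
   the KAS III *reaction* is absorbed by route redistribution: sampled
   distributions of the Δ12/Δ15 desaturases and ALA output do not shift.
5. **The membrane-incorporation sink sits on C18:1**, downstream of the
   Δ9 desaturase and upstream of Δ12. Forcing the elongation reaction
   therefore forces the Δ9 desaturase (surplus C18:0 has no other exit)
   and shifts the saturated chain upward in sampling, reproducing the
   elongation-vs-initiation asymmetry of over-expression interventions.

The toy does not emulate: regulation, maintenance energy demands
calibrated to data, realistic P/O or quantum yields, absolute growth
rates of any real organism, or genome-scale network redundancy. Passing
tests therefore demonstrate that the *algorithms* recover planted
structural truths, not that any real strain behaves this way.

Condition bounds mirror the published condition table: carboxylation
lower bounds 1.46 / 1.8 / 1.73 mmol gDW⁻¹ h⁻¹ and forced uptakes of
0.257 (acetate) and 0.175 (glucose), applied through the transporter in
its forward orientation and matched at the exchange with the
negative-uptake flag. The photon budget (100 mmol gDW⁻¹ h⁻¹) and all
stoichiometric coefficients are fixed constants of the generator and part
of its test contract.

The label-noise generator flips each in-silico essentiality label with a
configured probability (seeded) and marks a chosen number of genes
ambiguous, emulating an imperfect experimental screen; measured accuracy
then recovers 1 − ε up to binomial noise, which the tests check against
the exact 99% binomial interval at ε = 0.1 over 500 genes (a gene-inflated
variant of the toy attaches extra genes as dispensable isozymes and
indispensable complex members in equal parts).

## Problem sizes and determinism

The shipped analyses run on the 41-reaction toy: the full pipeline
(nine stages) takes a few seconds, the test suite about half a minute.
Sampling uses 600–2000 points, the GA 24–40 individuals for 12–25
generations, and design enumeration covers all subsets of the
six-candidate pool. All randomness flows from explicit seeds
(`numpy.random.default_rng`); HiGHS is deterministic, so pipeline reruns
with the same config and seed are byte-identical outside the manifest's
wall-clock entries.

## Known limitations

- SBML-FBC support is import (plus a round-trip export used in testing);
  models with features beyond bounds/GPRs/objective (e.g. flux objectives
  with coefficients ≠ 1, user-defined units) are reduced to this core.
- The GA is a deliberately small implementation for desk-scale candidate
  pools; it is validated against exhaustive enumeration only up to the
  sizes the tests exercise.
- `compare_distributions` is a summary heuristic, not a statistical test;
  with very large sample counts its 2×SE threshold will flag tiny
  geometric shifts.
- Flux sampling assumes a bounded polytope; models with unbounded rays
  (e.g. open exchanges at ±∞) must be bounded first.
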