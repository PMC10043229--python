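"""FSEOF scanning, model reduction, knockout enumeration and the GA
coupling search, cross-checked against exhaustive oracles."""

import itertools

import pytest

from cyanoflux import (FSEOFConfig, GAParams, coupling_strength,
                       enumerate_knockouts, evaluate_design, fseof,
                       ga_coupling_search, make_byproduct_toy,
                       make_two_sink_toy, max_growth, pareto_front,
                       reduce_for_design)
from cyanoflux.strain_design import _dominates


# ---------------------------------------------------------------------------
# FSEOF
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def miniphoto_scan(miniphoto):
    return fseof(miniphoto, "DM_ALA", FSEOFConfig(n_steps=6))


class TestFSEOF:
    def test_dedicated_precursor_is_a_target(self, two_sink):
        """The product's sole dedicated reaction must scale with enforced
        production (flux conservation)."""
        res = fseof(two_sink, "DM_PROD",
                    FSEOFConfig(min_biomass_fraction=0.5, n_steps=5))
        assert res.classification["DM_PROD"] == "target"

    def test_competing_sink_is_an_anti_target(self, two_sink):
        """Biomass competes for the shared precursor: its attainable flux
        falls as product formation is enforced (hand-solved two-sink LP)."""
        res = fseof(two_sink, "DM_PROD",
                    FSEOFConfig(min_biomass_fraction=0.5, n_steps=5))
        assert res.classification["BIOMASS"] == "anti-target"

    def test_enforced_target_is_always_classified_target(self, miniphoto_scan):
        assert miniphoto_scan.classification["DM_ALA"] == "target"

    def test_carboxylase_and_elongation_are_targets(self, miniphoto_scan):
        """Acetyl-CoA carboxylase and the FabF-like elongation step feed
        every ALA molecule and must be over-expression targets."""
        assert "ACCOAC" in miniphoto_scan.targets
        assert "3OAS180" in miniphoto_scan.targets

    def test_desaturases_are_targets(self, miniphoto_scan):
        for rxn in ("DESAT18a", "DES12", "DES15"):
            assert rxn in miniphoto_scan.targets

    def test_amino_acid_sink_is_anti_target(self, miniphoto_scan):
        assert "AAS" in miniphoto_scan.anti_targets

    def test_every_reaction_in_exactly_one_class(self, miniphoto, miniphoto_scan):
        assert set(miniphoto_scan.classification) == set(miniphoto.reaction_ids)
        assert set(miniphoto_scan.classification.values()) <= {
            "target", "anti-target", "unaffected"}

    def test_infeasible_biomass_fraction_rejected(self, two_sink):
        with pytest.raises(ValueError):
            fseof(two_sink, "DM_PROD", FSEOFConfig(min_biomass_fraction=2.0))

    def test_zero_capacity_target_rejected(self, two_sink):
        closed = two_sink.set_bounds("DM_PROD", 0.0, 0.0)
        with pytest.raises(ValueError):
            fseof(closed, "DM_PROD")


# ---------------------------------------------------------------------------
# Reduction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def candidates(miniphoto):
    from cyanoflux import classify_essential, single_gene_deletion
    screen = classify_essential(single_gene_deletion(miniphoto))
    essential = {g for g, lab in screen.items() if lab == "essential"}
    return reduce_for_design(miniphoto, essential)


class TestReduceForDesign:
    def test_exchange_reactions_excluded(self, candidates):
        assert not any(c.startswith(("EX_", "DM_", "SK_")) for c in candidates)

    def test_transport_reactions_excluded(self, candidates):
        for rxn in ("PHOt", "CO2t", "O2t", "ACtex", "GLCtex", "NO3t"):
            assert rxn not in candidates

    def test_orphans_excluded(self, candidates):
        assert "ATPM" not in candidates

    def test_essential_gene_reactions_excluded(self, candidates):
        for rxn in ("PSIIum", "RBPCcx", "ACCOAC", "3OAS180", "KAS15",
                    "ACOATA", "NAR"):
            assert rxn not in candidates

    def test_blocked_reactions_excluded(self, candidates):
        # acetate/glucose catabolism is blocked in the base medium
        assert "ACS" not in candidates
        assert "GLK" not in candidates

    def test_candidate_list_matches_hand_enumeration(self, candidates):
        """Applying the four reduction rules by hand leaves exactly the
        dispensable internal enzymatic reactions."""
        assert sorted(candidates) == ["AAS", "CS", "DES12", "DES15",
                                      "DESAT18a", "PDH"]


# ---------------------------------------------------------------------------
# Coupling strength
# ---------------------------------------------------------------------------

class TestCouplingStrength:
    def test_ala_is_not_growth_coupled(self, miniphoto):
        assert coupling_strength(miniphoto, "DM_ALA") == \
            pytest.approx(0.0, abs=1e-5)

    def test_stoichiometric_byproduct_is_coupled(self):
        """Biomass co-produces the byproduct at a fixed yield, so the
        minimum production at mu_max equals yield x mu_max."""
        toy = make_byproduct_toy(yield_coeff=0.5)
        mu = max_growth(toy)
        assert coupling_strength(toy, "DM_Q") == \
            pytest.approx(0.5 * mu, rel=1e-6)

    def test_biomass_self_coupling_equals_mu_max(self, miniphoto):
        mu = max_growth(miniphoto)
        assert coupling_strength(miniphoto, miniphoto.objective_reaction) == \
            pytest.approx(mu, rel=1e-5)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

MINIPHOTO_CANDIDATES = ["AAS", "CS", "DES12", "DES15", "DESAT18a", "PDH"]


class TestEnumerateKnockouts:
    def test_empty_candidates_rejected(self, miniphoto):
        with pytest.raises(ValueError):
            enumerate_knockouts(miniphoto, "DM_ALA", 1, [])

    def test_no_single_knockout_couples_ala(self, miniphoto):
        """Exhaustively over all single knockouts: none raises the ALA flux
        at maximal growth above the (zero) wild-type level."""
        ranked, meta = enumerate_knockouts(
            miniphoto, "DM_ALA", 1, MINIPHOTO_CANDIDATES, min_growth=1e-3)
        assert meta["mode"] == "exhaustive"
        for cand in ranked:
            assert cand.product_at_max_growth == pytest.approx(0.0, abs=1e-5)

    def test_removing_forced_overflow_raises_product(self):
        """With a forced wasteful drain on the precursor, deleting the
        overflow reaction restores the full production envelope."""
        toy = make_two_sink_toy(overflow_lb=2.0)
        wild = evaluate_design(toy, "DM_PROD", [], min_growth=1.0)
        ranked, _ = enumerate_knockouts(toy, "DM_PROD", 1,
                                        ["OVERFLOW", "DM_PROD"],
                                        min_growth=1.0)
        best = ranked[0]
        assert best.knockouts == frozenset({"OVERFLOW"})
        assert best.max_product > wild.max_product + 1.0

    def test_metrics_recomputable_from_model_and_set(self, miniphoto):
        ranked, _ = enumerate_knockouts(miniphoto, "DM_ALA", 2,
                                        MINIPHOTO_CANDIDATES[:4],
                                        min_growth=1e-3)
        probe = ranked[0]
        again = evaluate_design(miniphoto, "DM_ALA", probe.knockouts,
                                min_growth=1e-3)
        assert again == probe

    def test_supersets_never_beat_best_smaller_set_unfairly(self, miniphoto):
        """The k=2 ranking is at least as good as the k=1 ranking because
        every size-1 set is also admissible at k_max=2."""
        r1, _ = enumerate_knockouts(miniphoto, "DM_ALA", 1,
                                    MINIPHOTO_CANDIDATES, min_growth=1e-3)
        r2, _ = enumerate_knockouts(miniphoto, "DM_ALA", 2,
                                    MINIPHOTO_CANDIDATES, min_growth=1e-3)
        assert r2[0].sort_key() <= r1[0].sort_key()

    def test_beam_mode_engages_beyond_budget(self, miniphoto):
        ranked, meta = enumerate_knockouts(
            miniphoto, "DM_ALA", 2, MINIPHOTO_CANDIDATES,
            min_growth=1e-3, budget=3)
        assert meta["mode"] == "beam"
        assert "notice" in meta
        assert ranked                      # still produces designs


# ---------------------------------------------------------------------------
# GA coupling search
# ---------------------------------------------------------------------------

GA_TEST_PARAMS = GAParams(min_growth=1e-3, max_knockouts=5,
                          population_size=40, generation_limit=25, seed=7)


@pytest.fixture(scope="module")
def front(miniphoto):
    return ga_coupling_search(miniphoto, "DM_ALA", GA_TEST_PARAMS,
                              candidates=MINIPHOTO_CANDIDATES)


class TestGACouplingSearch:
    def test_no_growth_coupled_design_exists(self, front):
        """Even with every candidate knockable the front contains no design
        with positive coupling strength: ALA never enters biomass."""
        for cand in front:
            assert cand.product_at_max_growth == pytest.approx(0.0, abs=1e-5)

    def test_front_not_dominated_by_exhaustive_oracle(self, miniphoto, front):
        """No subset of candidates (exhaustive, sizes 0..5) dominates any
        front member."""
        oracle = []
        for k in range(0, 6):
            for combo in itertools.combinations(MINIPHOTO_CANDIDATES, k):
                cand = evaluate_design(miniphoto, "DM_ALA", combo,
                                       min_growth=1e-3)
                if cand is not None:
                    oracle.append(cand)
        oracle_front = pareto_front(oracle)
        for member in front:
            assert not any(_dominates(o, member) for o in oracle_front)
        # and every oracle-optimal objective vector is represented
        front_vectors = {(round(c.max_growth, 6), round(c.max_product, 6),
                          round(c.product_at_max_growth, 6)) for c in front}
        for o in oracle_front:
            vec = (round(o.max_growth, 6), round(o.max_product, 6),
                   round(o.product_at_max_growth, 6))
            assert vec in front_vectors

    def test_same_seed_same_front(self, miniphoto, front):
        again = ga_coupling_search(miniphoto, "DM_ALA", GA_TEST_PARAMS,
                                   candidates=MINIPHOTO_CANDIDATES)
        assert again == front

    def test_byproduct_toy_front_contains_coupled_wild_type(self):
        toy = make_byproduct_toy(yield_coeff=0.5)
        params = GAParams(min_growth=1e-3, max_knockouts=1,
                          population_size=8, generation_limit=5, seed=3)
        front = ga_coupling_search(toy, "DM_Q", params,
                                   candidates=["DM_Q"])
        empty = [c for c in front if not c.knockouts]
        assert empty and empty[0].product_at_max_growth > 1e-6

    def test_empty_pool_rejected(self, miniphoto):
        with pytest.raises(ValueError):
            ga_coupling_search(
                miniphoto, "DM_ALA",
                GAParams(population_size=4, generation_limit=2,
                         ignore_reactions=tuple(MINIPHOTO_CANDIDATES)),
                candidates=MINIPHOTO_CANDIDATES)
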