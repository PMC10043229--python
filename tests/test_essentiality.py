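"""Single-gene-deletion screen and the six validation statistics."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cyanoflux import (ConfusionCounts, apply_gene_knockout,
                       classify_essential, compute_stats, confusion,
                       make_essentiality_truth, make_toy_phototroph,
                       read_label_table, single_gene_deletion,
                       write_label_table)
from cyanoflux.essentiality import screen_report_rows
from cyanoflux.lp import optimize
from cyanoflux.synth import LabelNoiseConfig, ToyConfig

from .conftest import to_cobra


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

class TestComputeStats:
    def test_published_screen_counts_reproduce_reported_metrics(self):
        """A screen with TP=330, TN=333, FN=75, FP=37 yields accuracy 85.5%,
        sensitivity 81.5%, specificity 90.0%, precision 89.9% at one-decimal
        reporting precision."""
        s = compute_stats(ConfusionCounts(TP=330, TN=333, FP=37, FN=75))
        r = s.rounded()
        assert r["accuracy"] == 85.5
        assert r["sensitivity"] == 81.5
        assert r["specificity"] == 90.0
        assert r["precision"] == 89.9

    def test_hand_evaluated_small_table(self):
        """TP=3, TN=2, FP=1, FN=2 evaluated by hand from the definitions."""
        s = compute_stats(ConfusionCounts(TP=3, TN=2, FP=1, FN=2))
        assert s.accuracy == pytest.approx(62.5)
        assert s.sensitivity == pytest.approx(60.0)
        assert s.specificity == pytest.approx(100 * 2 / 3)
        assert s.precision == pytest.approx(75.0)
        assert s.f1_score == pytest.approx(2 * 3 / (2 * 3 + 1 + 2))

    def test_perfect_agreement_has_kappa_one(self):
        s = compute_stats(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert s.accuracy == 100.0
        assert s.kappa == 1.0

    def test_balanced_random_table_has_kappa_zero(self):
        s = compute_stats(ConfusionCounts(TP=5, TN=5, FP=5, FN=5))
        assert s.kappa == 0.0

    def test_zero_denominators_reported_as_undefined(self):
        s = compute_stats(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert s.sensitivity is None      # no experimentally essential genes
        assert s.precision is None        # nothing predicted essential
        assert s.specificity == 100.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    @given(st.tuples(*[st.integers(min_value=0, max_value=500)] * 4))
    def test_rational_identities(self, counts):
        """accuracy*N == 100(TP+TN) exactly; sensitivity and the miss rate
        sum to 100; kappa matches the printed closed form."""
        tp, tn, fp, fn = counts
        c = ConfusionCounts(tp, tn, fp, fn)
        if c.N == 0:
            return
        s = compute_stats(c)
        # accuracy * N == 100(TP+TN) in exact rationals: the float result
        # must equal the correctly rounded value of that exact fraction
        assert s.accuracy == float(Fraction(100 * (tp + tn), c.N))
        if tp + fn:
            miss = 100 * fn / (tp + fn)
            assert s.sensitivity + miss == pytest.approx(100.0)
        # printed closed form of the kappa denominator
        den = (tp * fn + tp * fp + 2 * tp * tn + fn * fn + fn * tn
               + fp * fp + fp * tn)
        if den:
            assert s.kappa == pytest.approx(2 * (tp * tn - fn * fp) / den)


# ---------------------------------------------------------------------------
# Classification and confusion
# ---------------------------------------------------------------------------

class TestClassification:
    def test_threshold_is_strict(self):
        growth = {"a": 0.0, "b": 1e-3, "c": 0.05, "d": 0.999e-3}
        labels = classify_essential(growth, threshold=1e-3)
        assert labels == {"a": "essential", "b": "non_essential",
                          "c": "non_essential", "d": "essential"}

    def test_relative_mode(self):
        growth = {"a": 0.04, "b": 0.5}
        labels = classify_essential(growth, threshold=0.1, relative_to=1.0)
        assert labels["a"] == "essential"
        assert labels["b"] == "non_essential"

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_essential({}, threshold=0.0)


class TestConfusion:
    def test_perfect_predictions(self):
        exp = {f"g{i}": "essential" for i in range(6)}
        exp.update({f"h{i}": "non_essential" for i in range(4)})
        counts = confusion(dict(exp), exp)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (6, 4, 0, 0)

    def test_ambiguous_gene_is_excluded(self):
        exp = {f"g{i}": "essential" for i in range(6)}
        exp.update({f"h{i}": "non_essential" for i in range(4)})
        pred = dict(exp)
        exp["g0"] = "ambiguous"
        counts = confusion(pred, exp)
        assert counts.N == 9

    def test_hand_tallied_disagreements(self):
        exp = {"a": "essential", "b": "essential", "c": "essential",
               "d": "non_essential", "e": "non_essential",
               "f": "non_essential", "g": "essential", "h": "non_essential"}
        pred = dict(exp)
        pred["c"] = "non_essential"       # one miss -> FN
        pred["d"] = "essential"           # one false call -> FP
        counts = confusion(pred, exp)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (3, 3, 1, 1)

    def test_genes_missing_from_either_table_excluded(self):
        pred = {"a": "essential", "b": "non_essential"}
        exp = {"b": "non_essential", "z": "essential"}
        assert confusion(pred, exp).N == 1

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            confusion({"a": "essential"}, {"b": "essential"})


# ---------------------------------------------------------------------------
# The in-silico screen
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def screen(miniphoto):
    return single_gene_deletion(miniphoto)


class TestScreen:
    def test_sole_precursor_gene_kills_growth(self, chain):
        growth = single_gene_deletion(chain)
        assert growth["g1"] == pytest.approx(0.0, abs=1e-9)

    def test_isozyme_gene_keeps_wild_type_growth(self, miniphoto, screen):
        from cyanoflux.lp import max_growth
        mu = max_growth(miniphoto)
        for g in ("gPDH1", "gPDH2", "gAAS1", "gAAS2"):
            assert screen[g] == pytest.approx(mu, rel=1e-6)

    def test_fatty_acid_chain_genes_are_essential(self, screen):
        """Biomass requires C18:0, so the initiation and elongation genes
        (FabH-like, FabF-like) and the carboxylase subunits are lethal."""
        for g in ("gKASH", "gKASF", "gACCa", "gACCd"):
            assert screen[g] == pytest.approx(0.0, abs=1e-9)

    def test_desaturase_genes_are_dispensable(self, screen):
        for g in ("gDESC", "gDESA", "gDESB"):
            assert screen[g] > 1e-3

    def test_screen_matches_reaction_closing_oracle(self, miniphoto, screen):
        """A gene is essential iff closing every reaction its knockout
        disables starves the biomass LP (brute-force cross-check)."""
        threshold = 1e-3
        for gene in miniphoto.genes:
            disabled = [r.id for r in miniphoto.reactions
                        if not r.gpr.is_empty()
                        and not r.gpr.evaluate({gene})]
            closed = miniphoto.knock_out_reactions(disabled)
            sol = optimize(closed)
            mu = sol.objective_value if sol.optimal else 0.0
            assert (screen[gene] < threshold) == (mu < threshold)

    def test_screen_matches_cobra(self, miniphoto, screen):
        """Essential calls agree with COBRApy's deletion analysis."""
        import cobra.flux_analysis as cfa
        cm = to_cobra(miniphoto)
        table = cfa.single_gene_deletion(cm)
        for _, row in table.iterrows():
            gene = next(iter(row["ids"]))
            mu = 0.0 if row["growth"] != row["growth"] else row["growth"]
            assert (screen[gene] < 1e-3) == (mu < 1e-3)

    def test_infeasible_wild_type_rejected(self, chain):
        dead = chain.set_bounds("EX_A", 0.0, 0.0)
        with pytest.raises(ValueError):
            single_gene_deletion(dead)


# ---------------------------------------------------------------------------
# Label tables, noise recovery and reports
# ---------------------------------------------------------------------------

class TestLabels:
    def test_round_trip(self, tmp_path):
        labels = {"a": "essential", "b": "ambiguous", "c": "untested",
                  "d": "non_essential"}
        path = tmp_path / "labels.tsv"
        write_label_table(labels, path)
        assert read_label_table(path) == labels

    def test_bad_label_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tlabel\ng1\tmaybe\n")
        with pytest.raises(ValueError, match="maybe"):
            read_label_table(path)

    def test_noise_free_truth_agrees_perfectly(self, miniphoto):
        truth = make_essentiality_truth(
            miniphoto, LabelNoiseConfig(flip_rate=0.0, seed=1))
        growth = single_gene_deletion(miniphoto)
        predicted = classify_essential(growth)
        counts = confusion(predicted, truth)
        assert counts.FP == counts.FN == 0
        assert compute_stats(counts).kappa == 1.0

    def test_ambiguous_count_is_respected(self, miniphoto):
        truth = make_essentiality_truth(
            miniphoto, LabelNoiseConfig(flip_rate=0.0, n_ambiguous=3, seed=2))
        assert sum(1 for v in truth.values() if v == "ambiguous") == 3
        growth = single_gene_deletion(miniphoto)
        counts = confusion(classify_essential(growth), truth)
        assert counts.N == len(miniphoto.genes) - 3

    def test_label_noise_recovery_within_binomial_interval(self):
        """Flipping true labels at rate 0.1 over 500 genes yields measured
        accuracy inside the exact binomial 99% interval around 90%."""
        model = make_toy_phototroph(ToyConfig(n_extra_genes=470))
        assert len(model.genes) == 501
        growth = single_gene_deletion(model)
        predicted = classify_essential(growth)
        truth = make_essentiality_truth(
            model, LabelNoiseConfig(flip_rate=0.1, seed=11),
            true_labels=predicted)
        counts = confusion(predicted, truth)
        n = counts.N
        lo, hi = sps.binom.interval(0.99, n, 0.9)
        assert lo <= counts.TP + counts.TN <= hi

    def test_screen_report_classes(self):
        growth = {"a": 0.0, "b": 0.5, "c": 0.5}
        pred = classify_essential(growth)
        exp = {"a": "essential", "b": "essential", "c": "ambiguous"}
        rows = {r["gene"]: r["class"]
                for r in screen_report_rows(growth, pred, exp)}
        assert rows == {"a": "TP", "b": "FN", "c": "excluded"}
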