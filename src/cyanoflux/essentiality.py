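"""Single-gene-deletion screen and its validation statistics.

A gene is called *essential in silico* when the growth rate of the single
knockout falls strictly below a threshold (default 1e-3 h^-1, interpreted as
an absolute growth rate; a relative-to-wild-type mode is available for
robustness studies).  Predictions are scored against experimental
essentiality labels with a 2x2 confusion matrix and six statistics:
accuracy, sensitivity, specificity, precision (as percentages), F1-score
and Cohen's kappa.

Confusion-count conventions: TP = predicted essential and experimentally
essential; TN = both non-essential; FP = predicted essential but
experimentally non-essential; FN = predicted non-essential but
experimentally essential.  Note that a published screen may describe its
discordant counts loosely in prose; here the counts are pinned down by the
sensitivity/specificity definitions (sensitivity uses FN, specificity uses
FP), so a reported (sensitivity, specificity) pair determines which
discordant count is which.

Genes labelled ``ambiguous`` or ``untested`` experimentally, and genes
absent from either table, are excluded before counting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional

from .lp import max_growth, optimize
from .model import MetabolicModel, apply_gene_knockout

ESSENTIALITY_THRESHOLD = 1e-3   # h^-1, growth below this = essential

EXPERIMENTAL_LABELS = ("essential", "non_essential", "ambiguous", "untested")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EssentialityStats:
    """Six screen-validation statistics; ``None`` marks an undefined metric
    (zero denominator), never coerced to 0."""
    accuracy: Optional[float]      # percent
    sensitivity: Optional[float]   # percent
    specificity: Optional[float]   # percent
    precision: Optional[float]     # percent
    f1_score: Optional[float]      # in [0, 1]
    kappa: Optional[float]         # in [-1, 1]

    def rounded(self, ndigits: int = 1) -> dict[str, Optional[float]]:
        """Percentages at reporting precision (1 decimal by default)."""
        out = {}
        for k in ("accuracy", "sensitivity", "specificity", "precision"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        out["f1_score"] = None if self.f1_score is None else round(self.f1_score, 4)
        out["kappa"] = None if self.kappa is None else round(self.kappa, 4)
        return out


def single_gene_deletion(model: MetabolicModel,
                         genes: Optional[list[str]] = None) -> dict[str, float]:
    """Knock out each gene in turn and record the mutant's maximal growth.

    Infeasible knockouts are reported as growth 0.  The wild type must be
    feasible (mu_max > 0).
    """
    mu_wt = max_growth(model)
    if mu_wt <= 0:
        raise ValueError(
            f"wild-type model {model.model_id!r} does not grow (mu_max={mu_wt})")
    if genes is None:
        genes = sorted(model.genes)
    out = {}
    for g in genes:
        mutant = apply_gene_knockout(model, {g})
        if mutant is model:                      # knockout touches no reaction
            out[g] = mu_wt
            continue
        sol = optimize(mutant, model.objective_reaction, "max")
        out[g] = sol.objective_value if sol.optimal else 0.0
    return out


def classify_essential(growth: Mapping[str, float],
                       threshold: float = ESSENTIALITY_THRESHOLD,
                       relative_to: Optional[float] = None) -> dict[str, str]:
    """Label genes essential iff knockout growth < threshold (strict).

    With ``relative_to`` set (wild-type growth), the threshold is applied to
    growth / relative_to instead of the absolute rate.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = {}
    for g, mu in growth.items():
        value = mu / relative_to if relative_to else mu
        out[g] = "essential" if value < threshold else "non_essential"
    return out


def confusion(predicted: Mapping[str, str],
              experimental: Mapping[str, str]) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix over the comparable gene set.

    Genes experimentally ambiguous/untested, or absent from either table,
    are excluded.
    """
    tp = tn = fp = fn = 0
    shared = set(predicted) & set(experimental)
    for g in shared:
        exp = experimental[g]
        if exp not in ("essential", "non_essential"):
            continue
        pred = predicted[g]
        if pred == "essential" and exp == "essential":
            tp += 1
        elif pred == "non_essential" and exp == "non_essential":
            tn += 1
        elif pred == "essential" and exp == "non_essential":
            fp += 1
        else:
            fn += 1
    counts = ConfusionCounts(tp, tn, fp, fn)
    if counts.N == 0:
        raise ValueError("no genes with unambiguous labels in both tables")
    return counts


def compute_stats(c: ConfusionCounts) -> EssentialityStats:
    """The six statistics; exact rational arithmetic, floats only at the end.

    kappa = 2 (TP TN - FN FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)),
    the closed form of Cohen's kappa for a 2x2 table.
    """
    TP, TN, FP, FN = c.TP, c.TN, c.FP, c.FN

    def pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else float(Fraction(100 * num, den))

    accuracy = pct(TP + TN, c.N)
    sensitivity = pct(TP, TP + FN)
    specificity = pct(TN, TN + FP)
    precision = pct(TP, TP + FP)
    f1 = None if (2 * TP + FP + FN) == 0 else \
        float(Fraction(2 * TP, 2 * TP + FP + FN))
    kden = (TP + FP) * (FP + TN) + (TP + FN) * (FN + TN)
    kappa = None if kden == 0 else \
        float(Fraction(2 * (TP * TN - FN * FP), kden))
    return EssentialityStats(accuracy, sensitivity, specificity, precision,
                             f1, kappa)


# ---------------------------------------------------------------------------
# Label table I/O and screen reports
# ---------------------------------------------------------------------------

def read_label_table(path) -> dict[str, str]:
    """TSV with header ``gene<TAB>label``; labels from the experimental set."""
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or \
                {"gene", "label"} - set(reader.fieldnames):
            raise ValueError(f"{path}: expected header 'gene\\tlabel'")
        for row in reader:
            label = row["label"].strip()
            if label not in EXPERIMENTAL_LABELS:
                raise ValueError(
                    f"{path}: unknown label {label!r} for gene {row['gene']!r}")
            out[row["gene"].strip()] = label
    return out


def write_label_table(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\n")
        for g in sorted(labels):
            fh.write(f"{g}\t{labels[g]}\n")


def screen_report_rows(growth: Mapping[str, float],
                       predicted: Mapping[str, str],
                       experimental: Mapping[str, str]) -> list[dict]:
    """Per-gene report rows with the confusion class of each gene."""
    rows = []
    for g in sorted(growth):
        exp = experimental.get(g, "untested")
        pred = predicted[g]
        if exp not in ("essential", "non_essential"):
            cls = "excluded"
        elif pred == "essential" and exp == "essential":
            cls = "TP"
        elif pred == "non_essential" and exp == "non_essential":
            cls = "TN"
        elif pred == "essential":
            cls = "FP"
        else:
            cls = "FN"
        rows.append({"gene": g, "knockout_growth": growth[g],
                     "predicted_label": pred, "experimental_label": exp,
                     "class": cls})
    return rows
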