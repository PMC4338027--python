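"""The ADVISER variant classification schema and its evaluation protocol.

The classic six-tier ACMG-style categorization is extended with starred
tiers 1*, 2* and 4* for finer stratification, ordered

    1 < 1* < 2 < 2* < 3 < 4 < 4* < 5 < 6

with lower meaning more clinically significant.  Two modes exist:
*clinical* considers only genes causally associated with a phenotype;
*research* additionally admits genes carrying statistically associated
risk variants and assigns category 6 to common reported risk factors.

Allele-frequency tiers: "rare" is max AF < 1%; "uncommon" is the closed
interval [1%, 5%]; boundaries belong to the starred tier.  A variant
absent from every reference population counts as AF 0 (rare).

Evaluation against a labeled set is threshold-or-better: a disease-labeled
variant is a true positive at threshold t iff its class is <= t in the
order above (so a class-2 variant is a false negative at threshold 1 and a
true positive at thresholds 2 and 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

__all__ = [
    "AdviserClass",
    "ClassifierInput",
    "ThresholdEvaluation",
    "CLASS_ORDER",
    "classify",
    "meets_threshold",
    "evaluate_thresholds",
    "classifier_input_from_columns",
]

CLASS_ORDER = ("1", "1*", "2", "2*", "3", "4", "4*", "5", "6")

TRUNCATING = ("nonsense", "frameshift")

#: effects whose impact is uncertain without a damaging prediction
UNCERTAIN_CODING = ("missense", "inframe_ins", "inframe_del", "splice_region")


@total_ordering
@dataclass(frozen=True)
class AdviserClass:
    value: str

    def __post_init__(self):
        if self.value not in CLASS_ORDER:
            raise ValueError(f"unknown ADVISER class {self.value!r}")

    @property
    def rank(self) -> int:
        return CLASS_ORDER.index(self.value)

    def __lt__(self, other):
        return self.rank < other.rank

    def __str__(self):
        return self.value


@dataclass(frozen=True)
class ClassifierInput:
    reported_pathogenic: bool = False
    reported_risk: bool = False
    gene_status: str = "none"        # clinical | research | none
    max_af: float | None = None      # None = unobserved, treated as 0
    effect: str = "noncoding"
    missense_damaging: bool = False
    truncation_damaging: bool = False
    splice_site_removed: bool = False

    def __post_init__(self):
        if self.gene_status not in ("clinical", "research", "none"):
            raise ValueError(f"bad gene_status {self.gene_status!r}")
        if self.max_af is not None and not 0.0 <= self.max_af <= 1.0:
            raise ValueError(f"max_af {self.max_af} outside [0,1]")
        if self.truncation_damaging and self.effect not in TRUNCATING:
            raise ValueError(
                "truncation_damaging set on a non-truncating effect")
        if self.missense_damaging and self.effect != "missense":
            raise ValueError("missense_damaging set on a non-missense effect")

    @property
    def truncating(self) -> bool:
        return self.effect in TRUNCATING


def classify(inp: ClassifierInput, mode: str = "clinical") -> AdviserClass:
    """Assign the ADVISER category; first matching rule wins.

    Rules 1/1*/2/2* follow the published tiering; tiers 3, 4, 4* and 5,
    and the placement of the risk rule 6 ahead of the benign fallback,
    are this package's documented refinement of the gradient from "most
    clinical relevance" down to "common risk factor".
    """
    if mode not in ("clinical", "research"):
        raise ValueError(f"unknown mode {mode!r}")
    af = 0.0 if inp.max_af is None else inp.max_af
    rare = af < 0.01
    uncommon = 0.01 <= af <= 0.05
    in_scope = inp.gene_status == "clinical" or (
        mode == "research" and inp.gene_status == "research")
    predicted_damaging = (inp.splice_site_removed or inp.missense_damaging
                          or inp.truncation_damaging)

    if inp.reported_pathogenic and rare:
        return AdviserClass("1")
    if inp.reported_pathogenic and uncommon:
        return AdviserClass("1*")
    if in_scope and not inp.reported_pathogenic:
        if rare and predicted_damaging:
            return AdviserClass("2")
        if (rare and inp.truncating and not inp.truncation_damaging) or \
                (uncommon and inp.truncating and inp.truncation_damaging):
            return AdviserClass("2*")
        if rare and inp.effect in UNCERTAIN_CODING:
            return AdviserClass("3")
    if not in_scope and rare:
        if predicted_damaging:
            return AdviserClass("4")
        if inp.effect in UNCERTAIN_CODING or inp.truncating:
            return AdviserClass("4*")
    if mode == "research" and inp.reported_risk and af > 0.05:
        return AdviserClass("6")
    return AdviserClass("5")


def meets_threshold(c: AdviserClass | str, threshold: AdviserClass | str) -> bool:
    """Threshold-or-better: true iff ``c`` <= ``threshold`` in the total
    order (the threshold "1-2" is class 2 and includes 1, 1* and 2)."""
    if isinstance(c, str):
        c = AdviserClass(c)
    if isinstance(threshold, str):
        threshold = AdviserClass(threshold)
    return c <= threshold


@dataclass(frozen=True)
class ThresholdEvaluation:
    threshold: AdviserClass
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2


def evaluate_thresholds(labeled, thresholds,
                        mode: str = "clinical") -> list[ThresholdEvaluation]:
    """Threshold-or-better evaluation of the classifier on a labeled set
    of ``(ClassifierInput, label)`` pairs, label in {disease, neutral}."""
    if not labeled:
        raise ValueError("labeled set is empty")
    calls = [(classify(inp, mode), label) for inp, label in labeled]
    out = []
    for t in thresholds:
        t = t if isinstance(t, AdviserClass) else AdviserClass(str(t))
        tp = fp = tn = fn = 0
        for c, label in calls:
            meets = meets_threshold(c, t)
            if label == "disease":
                tp, fn = tp + meets, fn + (not meets)
            elif label == "neutral":
                fp, tn = fp + meets, tn + (not meets)
            else:
                raise ValueError(f"unknown label {label!r}")
        out.append(ThresholdEvaluation(t, tp, fp, tn, fn))
    return out


# ---------------------------------------------------------------------------
# bridge from annotation columns

SEVERITY = (
    "nonsense", "frameshift", "splice_donor", "splice_acceptor", "missense",
    "inframe_ins", "inframe_del", "splice_region", "synonymous", "utr5",
    "utr3", "intronic", "noncoding",
)


def most_severe(effects) -> str | None:
    ranked = [e for e in effects if e in SEVERITY]
    return min(ranked, key=SEVERITY.index) if ranked else None


def classifier_input_from_columns(cols: dict) -> ClassifierInput:
    """Build a ClassifierInput from an annotation-column dict, using each
    variant's most severe transcript effect and its paired predictions."""
    effects = cols.get("effect") or []
    worst = most_severe(effects) or "noncoding"
    idx = effects.index(worst) if worst in effects else None

    def flag(name):
        vals = cols.get(name) or []
        return idx is not None and idx < len(vals) and vals[idx] is not None

    trunc_damaging = False
    if worst in TRUNCATING and flag("truncationScore"):
        from .predictors import TRUNCATION_DAMAGING
        trunc_damaging = float(
            cols["truncationScore"][idx]) >= TRUNCATION_DAMAGING
    missense_damaging = worst == "missense" and flag("missenseDamaging") and \
        cols["missenseDamaging"][idx] == "damaging"
    af = cols.get("maxAF")
    return ClassifierInput(
        reported_pathogenic=cols.get("pathogenic") == "pathogenic",
        reported_risk=cols.get("risk") == "risk",
        gene_status=cols.get("geneStatus") or "none",
        max_af=None if af in (None, "-") else float(af),
        effect=worst,
        missense_damaging=missense_damaging,
        truncation_damaging=trunc_damaging,
        splice_site_removed=worst in ("splice_donor", "splice_acceptor"),
    )
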