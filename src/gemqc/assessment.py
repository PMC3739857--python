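"""Benchmark model phenotype predictions against curated gene lists.

Orientation: "positive" means *predicted growth* (mutant viable).  A
true positive is a correctly predicted viable deletion of an inessential
gene; a true negative is a correctly predicted lethal deletion of an
essential gene.  MCC is orientation-invariant but sensitivity is not, so
this convention matters when reading reports.

Ratio metrics (sensitivity, specificity, PPV, NPV, geometric-mean
accuracy) return ``nan`` when their denominator vanishes — never a
silent 0.  MCC uses the documented convention of 0 for a vanishing
denominator (the binary-correlation limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InfeasibleError, UnknownIdentifierError
from .fba_engine import DEFAULT_GROWTH_THRESHOLD, check_growth, fba, single_gene_deletions
from .model import Model
from .network_core import Medium, apply_deletion, apply_medium, find_exchange_reactions


@dataclass
class ContingencyTable:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def scaled(self, k: int) -> "ContingencyTable":
        return ContingencyTable(self.tp * k, self.fp * k, self.tn * k, self.fn * k)


def build_contingency(predicted_viable: set[str], truth_essential: set[str],
                      universe: set[str]) -> ContingencyTable:
    """Contingency table over ``universe`` (positive = predicted viable).

    TP: predicted viable and truly inessential; FP: predicted viable but
    essential; TN: predicted lethal and essential; FN: predicted lethal
    but inessential.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    strays = set(predicted_viable) - universe
    if strays:
        raise UnknownIdentifierError(
            f"predicted set contains genes outside the universe: {sorted(strays)}"
        )
    essential = set(truth_essential) & universe
    inessential = universe - essential
    viable = set(predicted_viable)
    lethal = universe - viable
    return ContingencyTable(
        tp=len(viable & inessential),
        fp=len(viable & essential),
        tn=len(lethal & essential),
        fn=len(lethal & inessential),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def sensitivity(t: ContingencyTable) -> float:
    """TP / (TP + FN)."""
    return _ratio(t.tp, t.tp + t.fn)


def specificity(t: ContingencyTable) -> float:
    """TN / (TN + FP)."""
    return _ratio(t.tn, t.tn + t.fp)


def ppv(t: ContingencyTable) -> float:
    """TP / (TP + FP) — positive predictive value (precision)."""
    return _ratio(t.tp, t.tp + t.fp)


def npv(t: ContingencyTable) -> float:
    """TN / (TN + FN) — negative predictive value."""
    return _ratio(t.tn, t.tn + t.fn)


def mcc(t: ContingencyTable) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any factor of
    the denominator vanishes."""
    den2 = (t.tp + t.fp) * (t.tp + t.fn) * (t.tn + t.fp) * (t.tn + t.fn)
    if den2 == 0:
        return 0.0
    return (t.tp * t.tn - t.fp * t.fn) / math.sqrt(den2)


def geometric_mean_accuracy(t: ContingencyTable) -> float:
    """sqrt(sensitivity * specificity); nan if either is undefined."""
    sens, spec = sensitivity(t), specificity(t)
    if math.isnan(sens) or math.isnan(spec):
        return math.nan
    return math.sqrt(sens * spec)


def all_metrics(t: ContingencyTable) -> dict[str, float]:
    return {
        "tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn,
        "sensitivity": sensitivity(t),
        "specificity": specificity(t),
        "ppv": ppv(t),
        "npv": npv(t),
        "mcc": mcc(t),
        "geometric_mean_accuracy": geometric_mean_accuracy(t),
    }


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

@dataclass
class EssentialityResult:
    table: ContingencyTable
    metrics: dict[str, float]
    per_gene: pd.DataFrame
    universe: set[str]
    excluded_genes: set[str]  # benchmark genes absent from the model
    threshold: float


def essentiality_benchmark(model: Model, medium: Medium | None,
                           essential_list: set[str], verified_orfs: set[str],
                           threshold: float = DEFAULT_GROWTH_THRESHOLD
                           ) -> EssentialityResult:
    """Single-gene-deletion screen scored against an essentiality truth list.

    The evaluation universe is (model genes) ∩ (verified ORFs); benchmark
    genes outside the model cannot change FBA outcomes and are excluded
    but disclosed.
    """
    constrained = apply_medium(model, medium) if medium is not None else model
    wild = fba(constrained)
    if not wild.optimal or wild.objective_value < threshold:
        raise InfeasibleError("model does not grow on the benchmark medium")
    universe = set(model.genes) & set(verified_orfs)
    if not universe:
        raise ValueError("empty evaluation universe (no verified ORFs in model)")
    excluded = (set(verified_orfs) | set(essential_list)) - set(model.genes)
    outcomes = single_gene_deletions(constrained, sorted(universe), threshold)
    predicted_viable = {o.gene_id for o in outcomes if o.classification == "viable"}
    table = build_contingency(predicted_viable, set(essential_list), universe)
    rows = [
        (o.gene_id, o.growth_rate, o.classification,
         "essential" if o.gene_id in essential_list else "inessential")
        for o in outcomes
    ]
    per_gene = pd.DataFrame(
        rows, columns=["gene", "growth_rate", "predicted", "observed"]
    )
    return EssentialityResult(
        table=table, metrics=all_metrics(table), per_gene=per_gene,
        universe=universe, excluded_genes=excluded, threshold=threshold,
    )


@dataclass
class AuxotrophyReport:
    n_genes: int
    n_correct: int
    n_incorrect_viable_minimal: int
    n_incorrect_inviable_supplemented: int
    per_gene: pd.DataFrame = field(repr=False, default=None)

    def validate(self) -> None:
        if (self.n_correct + self.n_incorrect_viable_minimal
                + self.n_incorrect_inviable_supplemented) > self.n_genes:
            raise ValueError("auxotrophy class counts exceed gene count")


def default_supplemented_medium(model: Model, minimal: Medium,
                                uptake: float = -1.0) -> Medium:
    """Minimal medium plus uptake of every exchange metabolite not already
    consumed — the fallback when no gene-specific supplement is supplied."""
    bounds = dict(minimal.bounds)
    for rid in find_exchange_reactions(model):
        lb, ub = bounds.get(rid, (0.0, math.inf))
        if lb >= 0:
            bounds[rid] = (uptake, ub)
    return Medium(name=f"{minimal.name}+all", bounds=bounds)


def auxotrophy_benchmark(model: Model, auxotroph_genes: set[str],
                         minimal: Medium,
                         supplemented: dict[str, Medium] | None = None,
                         threshold: float = DEFAULT_GROWTH_THRESHOLD,
                         default_supplement: Medium | None = None
                         ) -> AuxotrophyReport:
    """Classify deletion mutants as auxotrophs per the two-condition rule.

    Correct: mutant fails on minimal AND grows on its supplemented
    medium.  Incorrectly viable: mutant grows on minimal.  Incorrectly
    inviable: mutant fails on both.
    """
    base_ok, _ = check_growth(model, minimal, threshold)
    if not base_ok:
        raise InfeasibleError("wild type does not grow on the minimal medium")
    supplemented = supplemented or {}
    if default_supplement is None:
        default_supplement = default_supplemented_medium(model, minimal)
    rows = []
    n_correct = n_viable_min = n_inviable_sup = 0
    for gene in sorted(auxotroph_genes):
        supp = supplemented.get(gene, default_supplement)
        if supp is None:
            raise UnknownIdentifierError(f"no supplemented medium for gene {gene!r}")
        mutant = apply_deletion(model, {gene})
        grows_min, _ = check_growth(mutant, minimal, threshold)
        grows_sup, _ = check_growth(mutant, supp, threshold)
        if grows_min:
            cls = "incorrect_viable_minimal"
            n_viable_min += 1
        elif grows_sup:
            cls = "correct"
            n_correct += 1
        else:
            cls = "incorrect_inviable_supplemented"
            n_inviable_sup += 1
        rows.append((gene, grows_min, grows_sup, cls))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "grows_minimal", "grows_supplemented", "class"]
    )
    report = AuxotrophyReport(
        n_genes=len(rows),
        n_correct=n_correct,
        n_incorrect_viable_minimal=n_viable_min,
        n_incorrect_inviable_supplemented=n_inviable_sup,
        per_gene=per_gene,
    )
    report.validate()
    return report


def read_gene_list(path) -> set[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
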