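"""Linear-programming core: FBA, gene-deletion screening, FVA, blocked reactions.

All LPs are solved with scipy's HiGHS interface over the sparse
stoichiometric matrix.  Optima are deterministic for a fixed model; flux
vectors at degenerate optima are advisory and may vary.

Tolerances: the solver runs at ``SOLVER_TOL``; classifications (growth /
blocked) use ``CLASSIFICATION_TOL``.  Both appear in report headers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .errors import ConfigurationError, InfeasibleError, SolverError, UnknownIdentifierError
from .model import DEFAULT_FLUX_CAP, Model
from .network_core import (
    Medium,
    apply_deletion,
    apply_medium,
    build_stoich_matrix,
    find_exchange_reactions,
)

SOLVER_TOL = 1e-9
CLASSIFICATION_TOL = 1e-6

#: Default growth-rate cutoff below which a deletion is called lethal.
DEFAULT_GROWTH_THRESHOLD = 1e-6


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    ranges: dict[str, tuple[float, float]]
    objective_fraction: float | None = None

    def blocked(self, tol: float = CLASSIFICATION_TOL) -> set[str]:
        return {
            rid for rid, (lo, hi) in self.ranges.items()
            if abs(lo) <= tol and abs(hi) <= tol
        }


@dataclass
class DeletionOutcome:
    gene_id: str
    growth_rate: float
    classification: str  # viable | lethal
    threshold: float
    in_model: bool = True


class _LpProblem:
    """Cached S matrix + bounds for repeated solves on one model."""

    def __init__(self, model: Model, cap: float = DEFAULT_FLUX_CAP * 1000):
        self.model = model
        self.stoich = build_stoich_matrix(model)
        self.rxn_ids = list(model.reactions)
        # HiGHS accepts infinite bounds directly; keep them.
        self.bounds = [
            (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
            for rid in self.rxn_ids
        ]
        self.n = len(self.rxn_ids)
        self.m = self.stoich.shape[0]

    def solve(self, c: np.ndarray, extra_A_ub=None, extra_b_ub=None):
        A_eq = self.stoich.matrix
        b_eq = np.zeros(self.m)
        res = linprog(
            c,
            A_eq=A_eq if self.m else None,
            b_eq=b_eq if self.m else None,
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=self.bounds,
            method="highs",
            options={"primal_feasibility_tolerance": SOLVER_TOL,
                     "dual_feasibility_tolerance": SOLVER_TOL},
        )
        return res


def _status_name(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 2:
        return "infeasible"
    if res.status == 3:
        return "unbounded"
    return "failed"


def fba(model: Model, *, objective_reaction: str | None = None) -> FluxResult:
    """Maximize (or minimize) flux through the objective under S v = 0.

    Raises :class:`ConfigurationError` when the model has no objective.
    """
    obj_id = objective_reaction or model.objective_reaction_id
    if obj_id is None:
        raise ConfigurationError("model has no objective reaction set")
    if obj_id not in model.reactions:
        raise UnknownIdentifierError(f"objective reaction {obj_id!r} not in model")
    prob = _LpProblem(model)
    sense = -1.0 if model.objective_sense == "maximize" else 1.0
    c = np.zeros(prob.n)
    c[prob.rxn_ids.index(obj_id)] = sense
    res = prob.solve(c)
    status = _status_name(res)
    if status == "failed":
        raise SolverError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return FluxResult(status=status, objective_value=math.nan)
    objective = float(res.fun) * sense
    fluxes = dict(zip(prob.rxn_ids, map(float, res.x)))
    return FluxResult(status="optimal", objective_value=objective, fluxes=fluxes)


def check_growth(model: Model, medium: Medium | None = None,
                 threshold: float = DEFAULT_GROWTH_THRESHOLD) -> tuple[bool, float]:
    """Whether the model grows (objective >= threshold) on a medium."""
    constrained = apply_medium(model, medium) if medium is not None else model
    result = fba(constrained)
    if not result.optimal:
        return False, 0.0
    return result.objective_value >= threshold, result.objective_value


def constrain_reaction(model: Model, reaction_id: str,
                       bounds: tuple[float, float]) -> Model:
    """Return a copy with one reaction's bounds replaced."""
    if reaction_id not in model.reactions:
        raise UnknownIdentifierError(f"unknown reaction {reaction_id!r}")
    lb, ub = bounds
    if lb > ub:
        raise ValueError(f"lower bound {lb} exceeds upper bound {ub}")
    out = model.copy()
    out.reactions[reaction_id].lower_bound = lb
    out.reactions[reaction_id].upper_bound = ub
    return out


def single_gene_deletions(model: Model, genes: list[str] | None = None,
                          threshold: float = DEFAULT_GROWTH_THRESHOLD
                          ) -> list[DeletionOutcome]:
    """Delete each gene in turn, re-solve, and classify viable/lethal.

    Genes absent from the model are reported viable at wild-type growth
    and flagged ``in_model=False``.  Deletions that close no reaction
    reuse the wild-type optimum without re-solving.
    """
    wild = fba(model)
    if not wild.optimal:
        raise InfeasibleError("wild-type model is not optimal; benchmark meaningless")
    if wild.objective_value < threshold:
        raise InfeasibleError(
            f"wild-type growth {wild.objective_value:.3g} below threshold {threshold:.3g}"
        )
    if genes is None:
        genes = list(model.genes)
    outcomes = []
    for gene in genes:
        if gene not in model.genes:
            outcomes.append(DeletionOutcome(
                gene_id=gene, growth_rate=wild.objective_value,
                classification="viable", threshold=threshold, in_model=False))
            continue
        deleted = frozenset((gene,))
        affected = [
            rid for rid, rxn in model.reactions.items()
            if gene in rxn.gpr.genes() and not rxn.gpr.evaluate(deleted)
        ]
        if not affected:
            growth, status = wild.objective_value, "optimal"
        else:
            mutant = apply_deletion(model, deleted)
            res = fba(mutant)
            growth = res.objective_value if res.optimal else 0.0
            status = res.status
        lethal = (status != "optimal") or (growth < threshold)
        outcomes.append(DeletionOutcome(
            gene_id=gene,
            growth_rate=0.0 if status != "optimal" else growth,
            classification="lethal" if lethal else "viable",
            threshold=threshold))
    return outcomes


def flux_variability(model: Model, objective_fraction: float | None = None
                     ) -> FvaResult:
    """Per-reaction LP minimum and maximum of flux.

    With ``objective_fraction`` f, adds the constraint
    objective >= f * (wild-type optimum).  Reactions are processed in
    column order for reproducible logs.
    """
    prob = _LpProblem(model)
    extra_A_ub = extra_b_ub = None
    if objective_fraction is not None:
        wild = fba(model)
        if not wild.optimal:
            raise InfeasibleError("cannot constrain objective: wild-type FBA not optimal")
        obj_col = prob.rxn_ids.index(model.objective_reaction_id)
        row = sp.csr_matrix(
            ([-1.0], ([0], [obj_col])), shape=(1, prob.n)
        )
        extra_A_ub = row
        extra_b_ub = np.array([-objective_fraction * wild.objective_value])

    ranges: dict[str, tuple[float, float]] = {}
    c = np.zeros(prob.n)
    for j, rid in enumerate(prob.rxn_ids):
        lb, ub = prob.bounds[j]
        if lb == ub:
            ranges[rid] = (lb, ub)
            continue
        c[j] = 1.0
        lo_res = prob.solve(c, extra_A_ub, extra_b_ub)
        c[j] = -1.0
        hi_res = prob.solve(c, extra_A_ub, extra_b_ub)
        c[j] = 0.0
        if lo_res.status == 2 or hi_res.status == 2:
            raise InfeasibleError("FVA base problem infeasible")
        lo = float(lo_res.fun) if lo_res.status == 0 else lb
        hi = float(-hi_res.fun) if hi_res.status == 0 else ub
        ranges[rid] = (min(lo, hi), max(lo, hi))
    return FvaResult(ranges=ranges, objective_fraction=objective_fraction)


def open_all_exchanges(model: Model, cap: float = DEFAULT_FLUX_CAP) -> Model:
    """Copy with every exchange reaction opened to (-cap, +cap)."""
    out = model.copy()
    for rid in find_exchange_reactions(out):
        out.reactions[rid].lower_bound = -cap
        out.reactions[rid].upper_bound = cap
    return out


def blocked_reactions(model: Model, *, cap: float = DEFAULT_FLUX_CAP,
                      tol: float = CLASSIFICATION_TOL) -> set[str]:
    """Reactions that can carry no flux anywhere in the feasible region.

    Evaluated with all exchanges opened to (-cap, +cap) and no objective
    constraint; a reaction is blocked iff both FVA extrema are zero
    within ``tol``.
    """
    opened = open_all_exchanges(model, cap)
    fva = flux_variability(opened, objective_fraction=None)
    return fva.blocked(tol)
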