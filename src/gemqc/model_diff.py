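"""Structured comparison of two reconstruction versions.

Comparison is identifier-based: the stable ``r_####`` / ``s_####`` id
scheme is shared across versions, so id equality is entity identity.
Constraint diffs compare (lower, upper) bound pairs of shared reactions;
by default serialized caps are normalized (|bound| >= cap compares as
infinite) so that ``1000`` and ``inf`` encodings agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import DEFAULT_FLUX_CAP, Model

BOUND_TOL = 1e-9


@dataclass
class DiffReport:
    metabolites_only_a: set[str] = field(default_factory=set)
    metabolites_only_b: set[str] = field(default_factory=set)
    metabolites_shared: set[str] = field(default_factory=set)
    reactions_only_a: set[str] = field(default_factory=set)
    reactions_only_b: set[str] = field(default_factory=set)
    reactions_shared: set[str] = field(default_factory=set)
    genes_only_a: set[str] = field(default_factory=set)
    genes_only_b: set[str] = field(default_factory=set)
    genes_shared: set[str] = field(default_factory=set)
    constraint_diffs: list[tuple[str, tuple[float, float], tuple[float, float]]] = \
        field(default_factory=list)

    def summary(self) -> dict[str, int]:
        return {
            "metabolites_only_a": len(self.metabolites_only_a),
            "metabolites_only_b": len(self.metabolites_only_b),
            "metabolites_shared": len(self.metabolites_shared),
            "reactions_only_a": len(self.reactions_only_a),
            "reactions_only_b": len(self.reactions_only_b),
            "reactions_shared": len(self.reactions_shared),
            "genes_only_a": len(self.genes_only_a),
            "genes_only_b": len(self.genes_only_b),
            "genes_shared": len(self.genes_shared),
            "constraint_diffs": len(self.constraint_diffs),
        }

    @property
    def is_empty(self) -> bool:
        return not (self.metabolites_only_a or self.metabolites_only_b
                    or self.reactions_only_a or self.reactions_only_b
                    or self.genes_only_a or self.genes_only_b
                    or self.constraint_diffs)


def _normalize_bound(value: float, cap: float | None) -> float:
    if cap is not None and math.isfinite(value) and abs(value) >= cap:
        return math.copysign(math.inf, value)
    return value


def _bounds_differ(a: tuple[float, float], b: tuple[float, float],
                   cap: float | None, tol: float) -> bool:
    for x, y in zip(a, b):
        x, y = _normalize_bound(x, cap), _normalize_bound(y, cap)
        if math.isinf(x) or math.isinf(y):
            if x != y:
                return True
        elif abs(x - y) > tol:
            return True
    return False


def diff_models(a: Model, b: Model, *, normalize_caps: bool = True,
                cap: float = DEFAULT_FLUX_CAP, tol: float = BOUND_TOL) -> DiffReport:
    """Identifier-based diff of two model versions.

    ``normalize_caps=False`` compares serialized bound values verbatim.
    """
    eff_cap = cap if normalize_caps else None
    mets_a, mets_b = set(a.metabolites), set(b.metabolites)
    rxns_a, rxns_b = set(a.reactions), set(b.reactions)
    genes_a, genes_b = set(a.genes), set(b.genes)
    report = DiffReport(
        metabolites_only_a=mets_a - mets_b,
        metabolites_only_b=mets_b - mets_a,
        metabolites_shared=mets_a & mets_b,
        reactions_only_a=rxns_a - rxns_b,
        reactions_only_b=rxns_b - rxns_a,
        reactions_shared=rxns_a & rxns_b,
        genes_only_a=genes_a - genes_b,
        genes_only_b=genes_b - genes_a,
        genes_shared=genes_a & genes_b,
    )
    for rid in sorted(report.reactions_shared):
        ba = a.reactions[rid].bounds
        bb = b.reactions[rid].bounds
        if _bounds_differ(ba, bb, eff_cap, tol):
            report.constraint_diffs.append((rid, ba, bb))
    return report


def summarize_model(model: Model, *, count_blocked: bool = False) -> dict:
    """Table-1-style summary counts for one model."""
    n_rxns = len(model.reactions)
    n_annotated = sum(1 for r in model.reactions.values() if r.pubmed_refs)
    summary = {
        "model_id": model.id,
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "reactions": n_rxns,
        "reactions_with_pmid": n_annotated,
        "pmid_coverage": (n_annotated / n_rxns) if n_rxns else 0.0,
    }
    if count_blocked:
        from .fba_engine import blocked_reactions
        blocked = blocked_reactions(model)
        summary["blocked_reactions"] = len(blocked)
        summary["blocked_fraction"] = (len(blocked) / n_rxns) if n_rxns else 0.0
    return summary
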