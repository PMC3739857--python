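"""Computable structures derived from a model.

Builds the sparse stoichiometric matrix, evaluates GPR trees under gene
deletions, applies growth media to exchange-reaction bounds, and
supports the reversibility-relaxation experiment.

All operations returning a model return a modified *copy*; inputs are
never mutated.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import scipy.sparse as sp

from .errors import ModelValidationError, UnknownIdentifierError
from .model import GeneAssociation, Model

#: Default uptake rate (mmol gDW^-1 h^-1) for supplemented compounds when
#: a medium file gives no explicit bound.
DEFAULT_SUPPLEMENT_UPTAKE = -1.0


@dataclass
class StoichMatrix:
    """Sparse stoichiometric matrix with id <-> index bijections.

    ``matrix[i, j]`` is the coefficient of metabolite ``i`` in reaction
    ``j`` (negative = consumed, positive = produced).
    """

    matrix: sp.csc_matrix
    row_index: dict[str, int]
    col_index: dict[str, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_stoich_matrix(model: Model) -> StoichMatrix:
    row_index = {mid: i for i, mid in enumerate(model.metabolites)}
    col_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows, cols, data = [], [], []
    for rid, rxn in model.reactions.items():
        j = col_index[rid]
        for mid, coef in rxn.stoichiometry.items():
            rows.append(row_index[mid])
            cols.append(j)
            data.append(coef)
    matrix = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(row_index), len(col_index))
    )
    return StoichMatrix(matrix=matrix, row_index=row_index, col_index=col_index)


def evaluate_gpr(gpr: GeneAssociation, deleted: set[str] | frozenset[str]) -> bool:
    """True iff the reaction remains catalysable after deleting ``deleted``.

    A leaf is true iff its gene survives; AND/OR follow boolean
    semantics; the EMPTY association is always true (reactions without
    gene annotation are unaffected by any deletion).
    """
    return gpr.evaluate(deleted)


def apply_deletion(model: Model, deleted: set[str]) -> Model:
    """Close every reaction whose GPR evaluates false under ``deleted``.

    Genes not present in the model are ignored (and retrievable via
    :func:`unknown_genes`); they cannot alter any GPR outcome.
    """
    deleted = frozenset(deleted)
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.gpr.is_empty() and not rxn.gpr.evaluate(deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def unknown_genes(model: Model, genes: set[str]) -> set[str]:
    """Subset of ``genes`` absent from the model (reported, never fatal)."""
    return set(genes) - model.genes.keys()


def find_exchange_reactions(model: Model) -> set[str]:
    """Reactions flagged ``is_exchange``, falling back to the structural
    single-metabolite criterion when no flag is set anywhere."""
    flagged = {rid for rid, rxn in model.reactions.items() if rxn.is_exchange}
    if flagged:
        return flagged
    return {rid for rid, rxn in model.reactions.items()
            if len(rxn.stoichiometry) == 1}


@dataclass
class Medium:
    """A named growth condition: bounds for exchange reactions.

    Exchanges are oriented metabolite -> (nothing), so uptake is a
    negative lower bound and secretion a positive upper bound.
    """

    name: str = "medium"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ModelValidationError(
                    f"medium {self.name!r}: bounds for {rid!r} have lb {lb} > ub {ub}"
                )

    def with_supplement(self, reaction_ids, uptake: float = DEFAULT_SUPPLEMENT_UPTAKE,
                        name: str | None = None) -> "Medium":
        """New medium allowing uptake through the given exchanges."""
        bounds = dict(self.bounds)
        for rid in reaction_ids:
            _, ub = bounds.get(rid, (0.0, math.inf))
            bounds[rid] = (uptake, ub)
        return Medium(name=name or f"{self.name}+supplement", bounds=bounds)


def apply_medium(model: Model, medium: Medium) -> Model:
    """Constrain exchange reactions to a growth condition.

    Listed exchanges receive the medium's bounds; every other exchange is
    set to ``(0, +inf)`` (secretion allowed, uptake forbidden).  Internal
    reactions are never touched.
    """
    medium.validate()
    out = model.copy()
    exchanges = find_exchange_reactions(out)
    missing = medium.bounds.keys() - out.reactions.keys()
    if missing:
        raise UnknownIdentifierError(
            f"medium {medium.name!r} references reactions absent from the model: "
            f"{sorted(missing)}"
        )
    non_exchange = medium.bounds.keys() - exchanges
    if non_exchange:
        raise UnknownIdentifierError(
            f"medium {medium.name!r} references non-exchange reactions: "
            f"{sorted(non_exchange)}"
        )
    for rid in exchanges:
        rxn = out.reactions[rid]
        if rid in medium.bounds:
            rxn.lower_bound, rxn.upper_bound = medium.bounds[rid]
        else:
            rxn.lower_bound, rxn.upper_bound = 0.0, math.inf
    return out


def relax_reversibility(model: Model, reaction_ids: set[str]) -> Model:
    """Make the listed reactions reversible: lower bound := -upper bound."""
    unknown = set(reaction_ids) - model.reactions.keys()
    if unknown:
        raise UnknownIdentifierError(
            f"cannot relax unknown reactions: {sorted(unknown)}"
        )
    out = model.copy()
    for rid in reaction_ids:
        rxn = out.reactions[rid]
        rxn.lower_bound = min(rxn.lower_bound, -rxn.upper_bound)
    return out


# ---------------------------------------------------------------------------
# medium files
# ---------------------------------------------------------------------------

def read_medium_tsv(path, name: str | None = None) -> Medium:
    """Load a medium from TSV columns (reaction_id, lower_bound, upper_bound).

    Lines starting with ``#`` and a header line are ignored; ``inf`` /
    ``-inf`` are accepted as bound values.
    """
    bounds: dict[str, tuple[float, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "reaction_id":
                continue
            if len(parts) != 3:
                raise ModelValidationError(
                    f"{path}: malformed medium line {line!r} "
                    "(expected reaction_id<TAB>lower<TAB>upper)"
                )
            bounds[parts[0]] = (float(parts[1]), float(parts[2]))
    medium = Medium(name=name or str(path), bounds=bounds)
    medium.validate()
    return medium


def write_medium_tsv(medium: Medium, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tlower_bound\tupper_bound\n")
        for rid, (lb, ub) in medium.bounds.items():
            fh.write(f"{rid}\t{lb}\t{ub}\n")


def load_preset_medium(name: str) -> Medium:
    """Load a shipped medium preset by stem name (e.g. ``anaerobic_minimal``).

    Presets target the consensus yeast id scheme and are best-effort
    reconstructions; override with a user TSV for exact conditions.
    """
    resource = importlib.resources.files("gemqc").joinpath("media", f"{name}.tsv")
    if not resource.is_file():
        available = sorted(
            p.name[:-4]
            for p in importlib.resources.files("gemqc").joinpath("media").iterdir()
            if p.name.endswith(".tsv")
        )
        raise UnknownIdentifierError(
            f"no medium preset {name!r}; available: {available}"
        )
    with importlib.resources.as_file(resource) as real_path:
        return read_medium_tsv(real_path, name=name)
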