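"""Domain types for constraint-based metabolic reconstructions.

A :class:`Model` holds compartments, metabolites, reactions (with flux
bounds and gene-protein-reaction boolean trees), genes and an optional
linear objective.  Flux bounds are stored internally as true floats with
``+/-inf`` meaning unbounded; the SBML writers cap infinities at the
conventional ``1000`` (see :data:`DEFAULT_FLUX_CAP`).

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed and positive for
produced species.  Exchange reactions are written ``metabolite -> (nothing)``
with coefficient ``-1``, so positive flux is secretion into the medium and
negative flux is uptake.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import FormatError, ModelValidationError

#: De-facto cap used when serializing unbounded fluxes (mmol gDW^-1 h^-1).
DEFAULT_FLUX_CAP = 1000.0


# ---------------------------------------------------------------------------
# Gene-protein-reaction boolean trees
# ---------------------------------------------------------------------------

class GeneAssociation:
    """Base class of the GPR expression tree.

    The tree is one of :class:`GprLeaf`, :class:`GprAnd`, :class:`GprOr`
    or the :data:`GPR_EMPTY` singleton.  ``EMPTY`` is the unique
    representation of "no gene annotation" and always evaluates true.
    """

    __slots__ = ()

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def is_empty(self) -> bool:
        return False

    def to_string(self) -> str:
        raise NotImplementedError


class GprEmpty(GeneAssociation):
    """No gene annotation; the reaction survives every deletion."""

    __slots__ = ()

    def evaluate(self, deleted) -> bool:
        return True

    def genes(self) -> frozenset[str]:
        return frozenset()

    def is_empty(self) -> bool:
        return True

    def to_string(self) -> str:
        return ""

    def __eq__(self, other):
        return isinstance(other, GprEmpty)

    def __hash__(self):
        return hash(GprEmpty)

    def __repr__(self):
        return "GPR_EMPTY"


#: Singleton used for reactions without a gene association.
GPR_EMPTY = GprEmpty()


class GprLeaf(GeneAssociation):
    __slots__ = ("gene_id",)

    def __init__(self, gene_id: str):
        if not gene_id:
            raise ValueError("gene id of a GPR leaf must be nonempty")
        self.gene_id = gene_id

    def evaluate(self, deleted) -> bool:
        return self.gene_id not in deleted

    def genes(self) -> frozenset[str]:
        return frozenset((self.gene_id,))

    def to_string(self) -> str:
        return self.gene_id

    def __eq__(self, other):
        return isinstance(other, GprLeaf) and self.gene_id == other.gene_id

    def __hash__(self):
        return hash(("leaf", self.gene_id))

    def __repr__(self):
        return f"GprLeaf({self.gene_id!r})"


class _GprNode(GeneAssociation):
    __slots__ = ("children",)
    _op = ""

    def __init__(self, children: Iterable[GeneAssociation]):
        kids = tuple(children)
        if len(kids) < 2:
            raise ValueError(f"{type(self).__name__} needs at least two children")
        if any(k.is_empty() for k in kids):
            raise ValueError("EMPTY may not appear inside a GPR tree")
        self.children = kids

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, _GprNode):
                s = f"({s})"
            parts.append(s)
        return f" {self._op} ".join(parts)

    def __eq__(self, other):
        return type(self) is type(other) and self.children == other.children

    def __hash__(self):
        return hash((self._op, self.children))

    def __repr__(self):
        return f"{type(self).__name__}({list(self.children)!r})"


class GprAnd(_GprNode):
    """All children required (enzyme-complex subunits)."""

    __slots__ = ()
    _op = "and"

    def evaluate(self, deleted) -> bool:
        return all(c.evaluate(deleted) for c in self.children)


class GprOr(_GprNode):
    """Any child suffices (isozymes)."""

    __slots__ = ()
    _op = "or"

    def evaluate(self, deleted) -> bool:
        return any(c.evaluate(deleted) for c in self.children)


_GPR_TOKEN = re.compile(r"\(|\)|\b[Aa][Nn][Dd]\b|\b[Oo][Rr]\b|&&?|\|\|?|[^\s()&|]+")


def parse_gpr(text: str) -> GeneAssociation:
    """Parse the textual GPR grammar ``"(A and B) or C"`` into a tree.

    Accepts ``and``/``or`` case-insensitively as well as the ``&``/``|``
    spellings found in some COBRA exports.  ``or`` binds looser than
    ``and``.  An empty or whitespace-only string yields :data:`GPR_EMPTY`.
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return GPR_EMPTY
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: str | None, name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and low in ("&", "&&")) or (
            name == "or" and low in ("|", "||")
        )

    def parse_or() -> GeneAssociation:
        terms = [parse_and()]
        while is_op(peek(), "or"):
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprOr(terms)

    def parse_and() -> GeneAssociation:
        terms = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else GprAnd(terms)

    def parse_atom() -> GeneAssociation:
        tok = peek()
        if tok is None:
            raise FormatError(f"GPR string ended unexpectedly: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise FormatError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise FormatError(f"unexpected token {tok!r} in GPR: {text!r}")
        return GprLeaf(take())

    tree = parse_or()
    if pos != len(tokens):
        raise FormatError(f"trailing tokens {tokens[pos:]!r} in GPR: {text!r}")
    return tree


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment_id: str = ""
    external_refs: list[tuple[str, str]] = field(default_factory=list)
    is_biomass: bool = False


@dataclass
class Gene:
    id: str
    standard_name: str = ""
    external_refs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -math.inf
    upper_bound: float = math.inf
    gpr: GeneAssociation = GPR_EMPTY
    pubmed_refs: list[str] = field(default_factory=list)
    is_exchange: bool = False

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class Model:
    """A genome-scale metabolic model (or bare reconstruction).

    ``metabolites``, ``reactions`` and ``genes`` are insertion-ordered
    mappings keyed by identifier; the order defines matrix row/column
    order downstream.
    """

    id: str = "model"
    name: str = ""
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    objective_reaction_id: str | None = None
    objective_sense: str = "maximize"
    dialect: str = "fbc3"

    # -- construction helpers ------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_gene(self, gene: Gene) -> Gene:
        if gene.id in self.genes:
            raise ModelValidationError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene
        return gene

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on the first violated invariant."""
        for met in self.metabolites.values():
            if not met.id:
                raise ModelValidationError("metabolite with empty id")
            if met.compartment_id and met.compartment_id not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r} references unknown compartment "
                    f"{met.compartment_id!r}"
                )
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            for met_id, coef in rxn.stoichiometry.items():
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
                if coef == 0 or not math.isfinite(coef):
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} has invalid coefficient {coef} "
                        f"for {met_id!r}"
                    )
            if rxn.is_exchange and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id!r} touches "
                    f"{len(rxn.stoichiometry)} metabolites (expected 1)"
                )
            unknown = rxn.gpr.genes() - self.genes.keys()
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR references unknown genes: "
                    f"{sorted(unknown)}"
                )
        if (
            self.objective_reaction_id is not None
            and self.objective_reaction_id not in self.reactions
        ):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if self.objective_sense not in ("maximize", "minimize"):
            raise ModelValidationError(
                f"invalid objective sense {self.objective_sense!r}"
            )

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions.values())


def models_equal(a: Model, b: Model, *, check_annotations: bool = True) -> bool:
    """Structural equality on ids, stoichiometry, bounds, GPRs and refs."""
    if a.metabolites.keys() != b.metabolites.keys():
        return False
    if a.reactions.keys() != b.reactions.keys():
        return False
    if a.genes.keys() != b.genes.keys():
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound) != (rb.lower_bound, rb.upper_bound):
            return False
        if ra.gpr != rb.gpr:
            return False
        if check_annotations and sorted(ra.pubmed_refs) != sorted(rb.pubmed_refs):
            return False
    if a.objective_reaction_id != b.objective_reaction_id:
        return False
    return True
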