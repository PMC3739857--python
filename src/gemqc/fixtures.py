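"""Deterministic synthetic reconstructions with known ground truth.

The generator builds small, LP-feasible toy models exercising every
behaviour the toolkit tests: a linear pathway to an explicit biomass
species, isozyme (OR) steps, dead-end metabolites (blocked reactions),
an auxotrophy branch rescued by a supplement exchange, and a two-route
energy branch (respiration vs fermentation analogue).

Topology is a pure function of the spec; the seed only permutes the
``s_####`` / ``r_####`` identifier assignment, so ground truth is
derivable by construction and identical specs + seeds serialize
byte-identically.

The module also ships naive brute-force oracles (dense simplex LPs,
sympy-based GPR evaluation) kept deliberately independent of
:mod:`gemqc.fba_engine` and :mod:`gemqc.network_core`.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from sympy import And as SymAnd, Or as SymOr, Symbol, true as sym_true

from .model import GPR_EMPTY, Gene, GprAnd, GprLeaf, GprOr, Metabolite, Model, Reaction
from .network_core import Medium


@dataclass
class ToyModelSpec:
    chain_length: int = 3
    n_isozyme_pairs: int = 0
    n_dead_ends: int = 0
    include_auxotroph_branch: bool = False
    include_energy_branch: bool = False
    seed: int = 0
    uptake_cap: float = 10.0

    def validate(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if self.n_isozyme_pairs < 0 or self.n_dead_ends < 0:
            raise ValueError("counts must be nonnegative")
        if self.uptake_cap <= 0:
            raise ValueError("uptake_cap must be positive")


@dataclass
class GroundTruth:
    """Construction-time bookkeeping for a generated toy model."""

    essential_genes: set[str] = field(default_factory=set)
    auxotroph_genes: set[str] = field(default_factory=set)
    blocked_reactions: set[str] = field(default_factory=set)
    exchange_ids: set[str] = field(default_factory=set)
    isozyme_pairs: list[tuple[str, str]] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)  # role -> id
    expected_growth: float = 0.0
    n_metabolites: int = 0
    n_reactions: int = 0
    n_genes: int = 0
    minimal_medium: Medium | None = None
    supplemented_medium: Medium | None = None

    def to_json(self) -> str:
        payload = {
            "essential_genes": sorted(self.essential_genes),
            "auxotroph_genes": sorted(self.auxotroph_genes),
            "blocked_reactions": sorted(self.blocked_reactions),
            "exchange_ids": sorted(self.exchange_ids),
            "isozyme_pairs": self.isozyme_pairs,
            "roles": self.roles,
            "expected_growth": self.expected_growth,
            "n_metabolites": self.n_metabolites,
            "n_reactions": self.n_reactions,
            "n_genes": self.n_genes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _orf_name(i: int) -> str:
    return f"YA{chr(65 + i % 26)}{i:03d}W"


def make_toy_model(spec: ToyModelSpec) -> tuple[Model, GroundTruth]:
    """Build a toy model and its ground truth from a spec.

    The network: a glucose-analogue exchange feeds a linear chain ending
    in a biomass-precursor metabolite consumed (1:1) by a biomass
    pseudo-reaction producing an explicit biomass species, drained by a
    biomass exchange.  Optional parts add isozyme OR-steps, dead-end
    metabolites, an auxotrophy branch and a respiration/fermentation
    energy branch.  The FBA objective is the biomass reaction.
    """
    spec.validate()
    gt = GroundTruth()

    # --- assemble with symbolic role names, renumber at the end ----------
    mets: list[tuple[str, str]] = []          # (role, display name)
    rxns: list[dict] = []
    genes: list[str] = []

    def met(role: str, name: str) -> str:
        mets.append((role, name))
        return role

    def gene(idx: int) -> str:
        g = _orf_name(idx)
        genes.append(g)
        return g

    def rxn(role: str, name: str, stoich: dict, gpr=GPR_EMPTY,
            lb: float = 0.0, ub: float = math.inf, exchange: bool = False):
        rxns.append(dict(role=role, name=name, stoich=stoich, gpr=gpr,
                         lb=lb, ub=ub, exchange=exchange))
        if exchange:
            gt.exchange_ids.add(role)

    gene_counter = 0
    glc = met("glc", "glucose analogue")
    rxn("glc_ex", "glucose exchange", {glc: -1.0},
        lb=-spec.uptake_cap, ub=math.inf, exchange=True)

    # linear chain, one essential gene per step
    prev = glc
    for i in range(spec.chain_length):
        nxt = met(f"chain_{i}", f"chain intermediate {i}")
        g = gene(gene_counter)
        gene_counter += 1
        rxn(f"chain_rxn_{i}", f"chain step {i}", {prev: -1.0, nxt: 1.0},
            gpr=GprLeaf(g))
        gt.essential_genes.add(g)
        prev = nxt

    # isozyme OR-steps extend the chain; neither gene is essential alone
    for k in range(spec.n_isozyme_pairs):
        nxt = met(f"iso_{k}", f"isozyme product {k}")
        ga, gb = gene(gene_counter), gene(gene_counter + 1)
        gene_counter += 2
        rxn(f"iso_rxn_{k}", f"isozyme step {k}", {prev: -1.0, nxt: 1.0},
            gpr=GprOr([GprLeaf(ga), GprLeaf(gb)]))
        gt.isozyme_pairs.append((ga, gb))
        prev = nxt

    biomass_substrates = {prev: -1.0}
    glc_per_growth = 1.0

    # dead ends: produced from glucose, never consumed, no exchange
    for d in range(spec.n_dead_ends):
        dead = met(f"dead_{d}", f"dead-end metabolite {d}")
        rxn(f"dead_rxn_{d}", f"dead-end producer {d}", {glc: -1.0, dead: 1.0})
        gt.blocked_reactions.add(f"dead_rxn_{d}")

    if spec.include_auxotroph_branch:
        aux = met("aux", "auxotrophy precursor")
        g_aux = gene(gene_counter)
        gene_counter += 1
        rxn("aux_syn", "precursor synthesis", {glc: -1.0, aux: 1.0},
            gpr=GprLeaf(g_aux))
        # supplement exchange: secretion-only by default (uptake closed)
        rxn("aux_ex", "precursor exchange", {aux: -1.0},
            lb=0.0, ub=math.inf, exchange=True)
        biomass_substrates[aux] = -1.0
        gt.auxotroph_genes.add(g_aux)
        gt.essential_genes.add(g_aux)  # essential while the supplement is closed
        glc_per_growth += 1.0

    if spec.include_energy_branch:
        o2 = met("o2", "oxygen analogue")
        atp = met("atp", "energy carrier")
        eth = met("eth", "fermentation byproduct")
        g_resp, g_ferm = gene(gene_counter), gene(gene_counter + 1)
        gene_counter += 2
        rxn("o2_ex", "oxygen exchange", {o2: -1.0},
            lb=-spec.uptake_cap, ub=math.inf, exchange=True)
        rxn("resp", "ATP synthase analogue (respiration)",
            {glc: -1.0, o2: -1.0, atp: 2.0}, gpr=GprLeaf(g_resp))
        rxn("ferm", "fermentation route", {glc: -1.0, atp: 1.0, eth: 1.0},
            gpr=GprLeaf(g_ferm))
        rxn("eth_ex", "byproduct exchange", {eth: -1.0},
            lb=0.0, ub=math.inf, exchange=True)
        biomass_substrates[atp] = -1.0
        glc_per_growth += 0.5  # respiration route: 2 ATP per glucose

    biomass = met("biomass", "biomass")
    rxn("biomass_rxn", "biomass pseudo-reaction",
        dict(biomass_substrates, **{biomass: 1.0}))
    rxn("biomass_ex", "biomass drain", {biomass: -1.0},
        lb=0.0, ub=math.inf, exchange=True)

    gt.expected_growth = spec.uptake_cap / glc_per_growth

    # --- seed-shuffled stable-id assignment ------------------------------
    rng = random.Random(spec.seed)
    met_numbers = list(range(1, len(mets) + 1))
    rxn_numbers = list(range(1, len(rxns) + 1))
    rng.shuffle(met_numbers)
    rng.shuffle(rxn_numbers)
    met_id = {role: f"s_{n:04d}" for (role, _), n in zip(mets, met_numbers)}
    rxn_id = {r["role"]: f"r_{n:04d}" for r, n in zip(rxns, rxn_numbers)}

    model = Model(id=f"toy_{spec.seed}", name="synthetic toy reconstruction",
                  compartments={"c": "cytoplasm"})
    for role, name in mets:
        model.add_metabolite(Metabolite(
            id=met_id[role], name=name, compartment_id="c",
            is_biomass=(role == "biomass")))
    for g in genes:
        model.add_gene(Gene(id=g))
    for r in rxns:
        model.add_reaction(Reaction(
            id=rxn_id[r["role"]], name=r["name"],
            stoichiometry={met_id[m]: c for m, c in r["stoich"].items()},
            lower_bound=r["lb"], upper_bound=r["ub"],
            gpr=r["gpr"], is_exchange=r["exchange"]))
    model.objective_reaction_id = rxn_id["biomass_rxn"]

    gt.roles = {**{f"met:{role}": mid for role, mid in met_id.items()},
                **{f"rxn:{role}": rid for role, rid in rxn_id.items()}}
    gt.exchange_ids = {rxn_id[r] for r in gt.exchange_ids}
    gt.blocked_reactions = {rxn_id[r] for r in gt.blocked_reactions}
    gt.n_metabolites = len(model.metabolites)
    gt.n_reactions = len(model.reactions)
    gt.n_genes = len(model.genes)

    minimal = {rxn_id["glc_ex"]: (-spec.uptake_cap, math.inf)}
    if spec.include_energy_branch:
        minimal[rxn_id["o2_ex"]] = (-spec.uptake_cap, math.inf)
    gt.minimal_medium = Medium(name="toy_minimal", bounds=minimal)
    if spec.include_auxotroph_branch:
        gt.supplemented_medium = gt.minimal_medium.with_supplement(
            [rxn_id["aux_ex"]], uptake=-spec.uptake_cap, name="toy_supplemented")

    model.validate()
    return model, gt


# ---------------------------------------------------------------------------
# brute-force oracles (independent code paths)
# ---------------------------------------------------------------------------

def _gpr_to_sympy(gpr):
    """Second-path GPR evaluation via a sympy boolean expression."""
    if gpr.is_empty():
        return sym_true
    if isinstance(gpr, GprLeaf):
        return Symbol(gpr.gene_id)
    op = SymAnd if isinstance(gpr, GprAnd) else SymOr
    return op(*[_gpr_to_sympy(c) for c in gpr.children])


def gpr_truth_table_eval(gpr, deleted: set[str]) -> bool:
    expr = _gpr_to_sympy(gpr)
    subs = {s: (str(s) not in deleted) for s in expr.free_symbols}
    return bool(expr.subs(subs))


def _dense_lp(model: Model, c: np.ndarray, bounds: list[tuple[float, float]]):
    """Dense-matrix simplex solve, formulated independently of fba_engine."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    A = np.zeros((len(met_ids), len(rxn_ids)))
    m_idx = {m: i for i, m in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            A[m_idx[mid], j] = coef
    return linprog(c, A_eq=A, b_eq=np.zeros(len(met_ids)), bounds=bounds,
                   method="highs-ds", options={"presolve": False})


def brute_force_essential(model: Model, threshold: float = 1e-6) -> set[str]:
    """Oracle for single-gene deletion screening.

    Loops every gene, closes failing reactions using the sympy GPR
    evaluator, and re-solves a dense LP.
    """
    rxn_ids = list(model.reactions)
    obj = model.objective_reaction_id
    if obj is None:
        raise ValueError("model has no objective")
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(obj)] = -1.0
    base_bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound)
                   for r in rxn_ids]
    essential: set[str] = set()
    for gene in model.genes:
        bounds = list(base_bounds)
        for j, rid in enumerate(rxn_ids):
            gpr = model.reactions[rid].gpr
            if not gpr.is_empty() and not gpr_truth_table_eval(gpr, {gene}):
                bounds[j] = (0.0, 0.0)
        res = _dense_lp(model, c, bounds)
        growth = -res.fun if res.status == 0 else 0.0
        if res.status != 0 or growth < threshold:
            essential.add(gene)
    return essential


def brute_force_blocked(model: Model, cap: float = 1000.0,
                        tol: float = 1e-6) -> set[str]:
    """Oracle for blocked-reaction detection: per-reaction dense min/max
    LPs with all single-metabolite reactions opened to (-cap, +cap)."""
    rxn_ids = list(model.reactions)
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        if len(rxn.stoichiometry) == 1:
            bounds.append((-cap, cap))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    blocked: set[str] = set()
    for j, rid in enumerate(rxn_ids):
        c = np.zeros(len(rxn_ids))
        c[j] = 1.0
        lo = _dense_lp(model, c, bounds)
        c[j] = -1.0
        hi = _dense_lp(model, c, bounds)
        lo_v = lo.fun if lo.status == 0 else -math.inf
        hi_v = -hi.fun if hi.status == 0 else math.inf
        if abs(lo_v) <= tol and abs(hi_v) <= tol:
            blocked.add(rid)
    return blocked


def write_fixture(model: Model, gt: GroundTruth, directory) -> dict[str, str]:
    """Write the fixture as SBML in both dialects plus a ground-truth JSON
    sidecar; returns the paths."""
    import os

    from .sbml_io import write_model

    os.makedirs(directory, exist_ok=True)
    paths = {
        "fbc3": os.path.join(directory, f"{model.id}_fbc3.xml"),
        "cobra_l2": os.path.join(directory, f"{model.id}_cobra_l2.xml"),
        "ground_truth": os.path.join(directory, f"{model.id}_truth.json"),
    }
    write_model(model, paths["fbc3"], "fbc3")
    write_model(model, paths["cobra_l2"], "cobra_l2")
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write(gt.to_json())
    return paths
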