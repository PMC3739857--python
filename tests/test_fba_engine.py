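import math

import numpy as np
import pytest

from gemqc.errors import ConfigurationError, InfeasibleError, UnknownIdentifierError
from gemqc.fba_engine import (
    blocked_reactions,
    check_growth,
    constrain_reaction,
    fba,
    flux_variability,
    open_all_exchanges,
    single_gene_deletions,
)
from gemqc.fixtures import (
    ToyModelSpec,
    brute_force_blocked,
    brute_force_essential,
    make_toy_model,
)
from gemqc.network_core import Medium, build_stoich_matrix

from conftest import SPEC_MATRIX


class TestFba:
    def test_chain_closed_form(self, chain_model):
        """1:1 chain fed by uptake <= 10 -> optimum exactly 10."""
        model, gt = chain_model
        res = fba(model)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(10.0, abs=1e-8)
        assert res.objective_value == pytest.approx(gt.expected_growth, abs=1e-8)

    def test_closed_medium_zero(self, chain_model):
        model, gt = chain_model
        rid = gt.roles["rxn:glc_ex"]
        model.reactions[rid].lower_bound = 0.0
        model.reactions[rid].upper_bound = 0.0
        res = fba(model)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("spec", SPEC_MATRIX, ids=lambda s: f"seed{s.seed}")
    def test_feasibility_of_solution(self, spec):
        """S v = 0 within 1e-6 and bounds respected for every fixture."""
        model, _ = make_toy_model(spec)
        res = fba(model)
        assert res.status == "optimal"
        sm = build_stoich_matrix(model)
        v = np.array([res.fluxes[rid] for rid in model.reactions])
        assert np.abs(sm.matrix @ v).max() <= 1e-6
        for rid, rxn in model.reactions.items():
            assert rxn.lower_bound - 1e-6 <= res.fluxes[rid] <= rxn.upper_bound + 1e-6

    @pytest.mark.parametrize("spec", SPEC_MATRIX, ids=lambda s: f"seed{s.seed}")
    def test_expected_growth_closed_form(self, spec):
        model, gt = make_toy_model(spec)
        res = fba(model)
        assert res.objective_value == pytest.approx(gt.expected_growth, rel=1e-9)

    def test_no_objective_errors(self, chain_model):
        model, _ = chain_model
        model.objective_reaction_id = None
        with pytest.raises(ConfigurationError):
            fba(model)

    def test_reproducible_optimum(self, rich_model):
        model, _ = rich_model
        values = {fba(model).objective_value for _ in range(3)}
        lo, hi = min(values), max(values)
        assert hi - lo <= 1e-6 * max(1.0, abs(hi))

    def test_monotonicity_under_bound_shrink(self, rich_model):
        """Shrinking any bound interval never increases the optimum."""
        model, _ = rich_model
        base = fba(model).objective_value
        for rid in list(model.reactions)[:8]:
            rxn = model.reactions[rid]
            lb = rxn.lower_bound if math.isfinite(rxn.lower_bound) else -50.0
            ub = rxn.upper_bound if math.isfinite(rxn.upper_bound) else 50.0
            mid_lo, mid_hi = lb + 0.25 * (ub - lb), lb + 0.75 * (ub - lb)
            shrunk = constrain_reaction(model, rid, (mid_lo, mid_hi))
            res = fba(shrunk)
            value = res.objective_value if res.optimal else 0.0
            assert value <= base + 1e-6


class TestSingleGeneDeletions:
    def test_matches_ground_truth(self, rich_model):
        model, gt = rich_model
        outcomes = single_gene_deletions(model)
        lethal = {o.gene_id for o in outcomes if o.classification == "lethal"}
        assert lethal == gt.essential_genes

    def test_sole_path_gene_lethal(self, chain_model):
        model, gt = chain_model
        gene = next(iter(gt.essential_genes))
        (outcome,) = single_gene_deletions(model, [gene])
        assert outcome.classification == "lethal"

    def test_isozyme_single_deletion_viable(self, rich_model):
        model, gt = rich_model
        ga, _ = gt.isozyme_pairs[0]
        wild = fba(model).objective_value
        (outcome,) = single_gene_deletions(model, [ga])
        assert outcome.classification == "viable"
        assert outcome.growth_rate == pytest.approx(wild, rel=1e-9)

    def test_gene_without_gpr_exactly_wildtype(self, chain_model):
        model, _ = chain_model
        from gemqc.model import Gene
        model.add_gene(Gene(id="YFREE001W"))
        wild = fba(model).objective_value
        (outcome,) = single_gene_deletions(model, ["YFREE001W"])
        assert outcome.classification == "viable"
        assert outcome.growth_rate == wild  # exact, not approximate

    def test_gene_not_in_model_flagged(self, chain_model):
        model, _ = chain_model
        (outcome,) = single_gene_deletions(model, ["YNOPE001W"])
        assert outcome.classification == "viable"
        assert not outcome.in_model

    def test_infeasible_wildtype_errors(self, chain_model):
        model, gt = chain_model
        rid = gt.roles["rxn:glc_ex"]
        model.reactions[rid].lower_bound = 0.0
        model.reactions[rid].upper_bound = 0.0
        with pytest.raises(InfeasibleError):
            single_gene_deletions(model)


class TestFva:
    def test_irreversible_chain_hand_lp(self, chain_model):
        """Every chain reaction: v in [0, cap]; forced flux only via objective."""
        model, gt = chain_model
        fva = flux_variability(model)
        cap = 10.0
        for role in ("chain_rxn_0", "chain_rxn_1", "chain_rxn_2", "biomass_rxn"):
            lo, hi = fva.ranges[gt.roles[f"rxn:{role}"]]
            assert lo == pytest.approx(0.0, abs=1e-8)
            assert hi == pytest.approx(cap, abs=1e-8)

    def test_fixed_zero_reaction(self, chain_model):
        model, gt = chain_model
        rid = gt.roles["rxn:chain_rxn_1"]
        model.reactions[rid].lower_bound = 0.0
        model.reactions[rid].upper_bound = 0.0
        fva = flux_variability(model)
        assert fva.ranges[rid] == (0.0, 0.0)

    def test_objective_fraction_pins_biomass(self, chain_model):
        model, gt = chain_model
        fva = flux_variability(model, objective_fraction=1.0)
        lo, hi = fva.ranges[gt.roles["rxn:biomass_rxn"]]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    def test_vmin_le_vmax_everywhere(self, rich_model):
        model, _ = rich_model
        fva = flux_variability(model)
        for lo, hi in fva.ranges.values():
            assert lo <= hi + 1e-9

    @pytest.mark.parametrize("spec", SPEC_MATRIX, ids=lambda s: f"seed{s.seed}")
    def test_matches_dense_oracle(self, spec):
        """FVA-based blocked detection equals the naive dense-LP oracle."""
        model, _ = make_toy_model(spec)
        assert len(model.reactions) <= 30
        assert blocked_reactions(model) == brute_force_blocked(model)


class TestBlockedReactions:
    def test_dead_end_producers_blocked(self):
        model, gt = make_toy_model(ToyModelSpec(chain_length=2, n_dead_ends=2, seed=9))
        assert blocked_reactions(model) == gt.blocked_reactions
        assert len(gt.blocked_reactions) == 2

    def test_fully_coupled_chain_unblocked(self, chain_model):
        model, _ = chain_model
        assert blocked_reactions(model) == set()

    def test_closed_reaction_blocked(self, chain_model):
        model, gt = chain_model
        rid = gt.roles["rxn:chain_rxn_1"]
        closed = constrain_reaction(model, rid, (0.0, 0.0))
        assert rid in blocked_reactions(closed)

    def test_relaxation_reduces_blocked_count(self):
        """Dead-end fluxes become feasible once a second producer is made
        reversible, giving the dead-end metabolite an outlet."""
        model, gt = make_toy_model(ToyModelSpec(chain_length=2, n_dead_ends=1, seed=4))
        from gemqc.model import Reaction
        from gemqc.network_core import relax_reversibility
        dead_rxn = gt.roles["rxn:dead_rxn_0"]
        dead_met = gt.roles["met:dead_0"]
        chain_met = gt.roles["met:chain_0"]
        model.add_reaction(Reaction(id="r_9000", name="second dead-end producer",
                                    stoichiometry={chain_met: -1.0, dead_met: 1.0},
                                    lower_bound=0.0, upper_bound=1000.0))
        before = blocked_reactions(model)
        assert {dead_rxn, "r_9000"} <= before
        relaxed = relax_reversibility(model, {"r_9000"})
        after = blocked_reactions(relaxed)
        assert dead_rxn not in after
        assert len(after) < len(before)


class TestCheckGrowthAndConstrain:
    def test_closed_carbon_no_growth(self, chain_model):
        model, gt = chain_model
        glc_ex = gt.roles["rxn:glc_ex"]
        closed = Medium(name="closed", bounds={glc_ex: (0.0, math.inf)})
        grows, rate = check_growth(model, closed)
        assert not grows
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_minimal_medium_growth(self, rich_model):
        model, gt = rich_model
        grows, rate = check_growth(model, gt.minimal_medium)
        assert grows
        assert rate == pytest.approx(gt.expected_growth, rel=1e-9)

    def test_anaerobic_analogue_needs_supplement(self):
        """Closing oxygen on an aux+energy toy with fermentation disabled
        mimics the no-growth / supplemented-growth pair qualitatively."""
        model, gt = make_toy_model(ToyModelSpec(
            chain_length=2, include_auxotroph_branch=True,
            include_energy_branch=True, seed=11))
        # make respiration the only ATP source matter: delete fermentation flux
        ferm = gt.roles["rxn:ferm"]
        model = constrain_reaction(model, ferm, (0.0, 0.0))
        o2_ex = gt.roles["rxn:o2_ex"]
        anaerobic = Medium(name="anaerobic", bounds={
            gt.roles["rxn:glc_ex"]: (-10.0, math.inf),
            o2_ex: (0.0, math.inf),
        })
        grows, _ = check_growth(model, anaerobic)
        assert not grows

    def test_constrain_identical_bounds_noop(self, chain_model):
        model, gt = chain_model
        rid = gt.roles["rxn:chain_rxn_0"]
        out = constrain_reaction(model, rid, model.reactions[rid].bounds)
        assert out.reactions[rid].bounds == model.reactions[rid].bounds
        assert fba(out).objective_value == pytest.approx(
            fba(model).objective_value, rel=1e-9)

    def test_constrain_unknown_or_invalid(self, chain_model):
        model, _ = chain_model
        with pytest.raises(UnknownIdentifierError):
            constrain_reaction(model, "r_9999", (0.0, 1.0))
        rid = next(iter(model.reactions))
        with pytest.raises(ValueError):
            constrain_reaction(model, rid, (5.0, -5.0))

    def test_atp_synthase_restriction_forces_fermentation(self):
        model, gt = make_toy_model(ToyModelSpec(
            chain_length=2, include_energy_branch=True, seed=13))
        resp, ferm = gt.roles["rxn:resp"], gt.roles["rxn:ferm"]
        wild = fba(model)
        assert wild.fluxes[resp] > 1e-6  # respiration preferred (better yield)
        restricted = constrain_reaction(model, resp, (0.0, 0.0))
        res = fba(restricted)
        assert res.status == "optimal"
        assert res.fluxes[ferm] > 1e-6
        assert res.objective_value < wild.objective_value


class TestOracleCrossChecks:
    @pytest.mark.parametrize("spec", SPEC_MATRIX, ids=lambda s: f"seed{s.seed}")
    def test_deletions_match_brute_force(self, spec):
        model, _ = make_toy_model(spec)
        lethal = {o.gene_id for o in single_gene_deletions(model)
                  if o.classification == "lethal"}
        assert lethal == brute_force_essential(model)
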