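"""Model domain types, structural validation, biomass switching."""

import pytest

from bofsens.gpr import parse_gpr
from bofsens.model import (
    ConstraintSet,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    set_active_biomass,
    validate_model,
)

from .oracles import graph_dead_ends


def chain_model(with_sink: bool) -> MetabolicModel:
    """A -> B -> C, optionally with an exchange draining C."""
    mets = [Metabolite(m, compartment="c") for m in ("A", "B", "C")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1}, lower_bound=-1,
                 upper_bound=0, is_exchange=True),
        Reaction(id="R1", stoichiometry={"A": -1, "B": 1}, lower_bound=0),
        Reaction(id="R2", stoichiometry={"B": -1, "C": 1}, lower_bound=0),
    ]
    if with_sink:
        rxns.append(Reaction(id="EX_C", stoichiometry={"C": -1},
                             lower_bound=-1000, is_exchange=True))
    return MetabolicModel(compartments=["c"], metabolites=mets, reactions=rxns)


class TestInvariants:
    def test_duplicate_metabolite_rejected(self):
        m = MetabolicModel(compartments=["c"])
        m.add_metabolite(Metabolite("A", compartment="c"))
        with pytest.raises(ModelValidationError):
            m.add_metabolite(Metabolite("A", compartment="c"))

    def test_unknown_compartment_rejected(self):
        m = MetabolicModel(compartments=["c"])
        with pytest.raises(ModelValidationError):
            m.add_metabolite(Metabolite("A", compartment="x"))

    def test_dangling_stoichiometry_rejected(self):
        m = MetabolicModel(compartments=["c"])
        m.add_metabolite(Metabolite("A", compartment="c"))
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            m.add_reaction(Reaction(id="R", stoichiometry={"A": -1, "Z": 1}))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="R", stoichiometry={"A": -1}, lower_bound=1,
                     upper_bound=-1)

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="EX", stoichiometry={"A": -1, "B": 1},
                     is_exchange=True)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="R", stoichiometry={})


class TestValidateModel:
    def test_chain_without_sink_flags_terminal_metabolite(self):
        report = validate_model(chain_model(with_sink=False))
        assert report.dead_end_metabolites == ["C"]

    def test_chain_with_sink_is_clean(self):
        report = validate_model(chain_model(with_sink=True))
        assert report.dead_end_metabolites == []

    def test_blocked_reactions_reported(self):
        m = chain_model(with_sink=True)
        m.reactions["R2"].bounds = (0.0, 0.0)
        report = validate_model(m)
        assert "R2" in report.blocked_reactions
        # with R2 blocked, B is no longer consumed (C keeps its
        # reversible exchange, which both produces and consumes it)
        assert set(report.dead_end_metabolites) == {"B"}

    def test_dead_ends_match_graph_oracle_on_fixture(self, core_model):
        assert set(validate_model(core_model).dead_end_metabolites) == \
            graph_dead_ends(core_model)

    def test_dead_end_set_invariant_under_reaction_reordering(self, core_model):
        baseline = validate_model(core_model).dead_end_metabolites
        reordered = MetabolicModel(
            model_id=core_model.id,
            compartments=core_model.compartments,
            metabolites=core_model.metabolites.values(),
            reactions=list(core_model.reactions.values())[::-1],
        )
        assert validate_model(reordered).dead_end_metabolites == baseline


class TestBiomassSwitching:
    def test_activation_clamps_all_other_biomasses(self, core_model):
        ids = sorted(core_model.biomass_registry)
        set_active_biomass(core_model, ids[1])
        active_rxn = core_model.biomass_registry[ids[1]]
        assert core_model.objective_id == active_rxn
        assert core_model.reactions[active_rxn].bounds == (0.0, 1000.0)
        for cid in ids:
            if cid != ids[1]:
                rxn = core_model.reactions[core_model.biomass_registry[cid]]
                assert rxn.bounds == (0.0, 0.0)

    def test_switching_is_idempotent(self, core_model):
        ids = sorted(core_model.biomass_registry)
        set_active_biomass(core_model, ids[0])
        snapshot = {r.id: r.bounds for r in core_model.reactions.values()}
        set_active_biomass(core_model, ids[1])
        set_active_biomass(core_model, ids[0])
        assert {r.id: r.bounds for r in core_model.reactions.values()} == snapshot

    def test_unknown_composition_lists_registered_ids(self, core_model):
        with pytest.raises(KeyError, match="wt_normoxic"):
            set_active_biomass(core_model, "no_such_composition")


class TestConstraintSet:
    def test_negative_magnitude_rejected(self):
        with pytest.raises(ModelValidationError):
            ConstraintSet(uptake={"EX_glc": -1.0})

    def test_uptake_maps_to_fixed_negative_bounds(self):
        cs = ConstraintSet(uptake={"EX_glc": 0.99})
        assert cs.bounds_map()["EX_glc"] == (-0.99, -0.99)

    def test_secretion_maps_to_minimum_secretion(self):
        cs = ConstraintSet(secretion={"EX_etoh": 0.31})
        assert cs.bounds_map()["EX_etoh"] == (0.31, 1000.0)

    def test_non_exchange_target_rejected(self, core_model):
        with pytest.raises(ModelValidationError):
            ConstraintSet(uptake={"R_glyco": 1.0}).validate_against(core_model)

    def test_unknown_target_rejected(self, core_model):
        with pytest.raises(KeyError):
            ConstraintSet(uptake={"EX_nope": 1.0}).validate_against(core_model)

    def test_gpr_parses_into_model_genes(self, core_model):
        assert "g_hxt1" in core_model.genes
        assert core_model.reactions["T_glc"].gpr == parse_gpr("g_hxt1 or g_hxt2")
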