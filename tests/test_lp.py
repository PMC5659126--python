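"""FBA and FVA against constructed cases and the dense-LP oracle."""

import numpy as np
import pytest

from bofsens.lp import InfeasibleProblemError, apply_constraints, fba, fva
from bofsens.model import ConstraintSet, MetabolicModel, Metabolite, Reaction
from bofsens.synthetic import FixtureSpec, core_constraints, generate_random_network

from .oracles import dense_fva, dense_lp

TOL = 1e-6


def linear_chain(internal_cap: float | None = None) -> MetabolicModel:
    """EX_A (fixed uptake 1) -> A -> B -> drain, unit stoichiometry."""
    mets = [Metabolite(m, compartment="c") for m in ("A", "B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1}, lower_bound=-1,
                 upper_bound=-1, is_exchange=True),
        Reaction(id="R_AB", stoichiometry={"A": -1, "B": 1}, lower_bound=0,
                 upper_bound=internal_cap if internal_cap else 1000.0),
        Reaction(id="DM_B", stoichiometry={"B": -1}, lower_bound=0,
                 is_exchange=True),
    ]
    return MetabolicModel(compartments=["c"], metabolites=mets,
                          reactions=rxns, objective_id="DM_B")


def diamond() -> MetabolicModel:
    """A -> B via two symmetric routes, total flux forced to 1."""
    mets = [Metabolite(m, compartment="c") for m in ("A", "B")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A": -1}, lower_bound=-1,
                 upper_bound=-1, is_exchange=True),
        Reaction(id="R2a", stoichiometry={"A": -1, "B": 1}, lower_bound=0),
        Reaction(id="R2b", stoichiometry={"A": -1, "B": 1}, lower_bound=0),
        Reaction(id="DM_B", stoichiometry={"B": -1}, lower_bound=0,
                 is_exchange=True),
    ]
    return MetabolicModel(compartments=["c"], metabolites=mets,
                          reactions=rxns, objective_id="DM_B")


class TestFba:
    def test_flux_conservation_along_a_path(self):
        sol = fba(linear_chain())
        assert sol.optimal
        assert sol.objective_value == pytest.approx(1.0, abs=TOL)

    def test_internal_bottleneck_caps_objective(self):
        # the uptake of 1 cannot pass a 0.4-capacity internal step, so
        # the fixed-uptake chain is infeasible; relax uptake to <= 1
        model = linear_chain(internal_cap=0.4)
        model.reactions["EX_A"].bounds = (-1, 0)
        sol = fba(model)
        assert sol.objective_value == pytest.approx(0.4, abs=TOL)

    def test_infeasible_status_reported_without_fluxes(self):
        model = linear_chain(internal_cap=0.4)  # uptake fixed at 1
        sol = fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {} and sol.objective_value is None

    def test_unbounded_status_reported(self):
        inf = float("inf")
        model = linear_chain()
        model.reactions["EX_A"].bounds = (-inf, inf)
        model.reactions["R_AB"].bounds = (-inf, inf)
        model.reactions["DM_B"].bounds = (-inf, inf)
        sol = fba(model, objective="DM_B", sense="min")
        assert sol.status == "unbounded"

    def test_steady_state_residual_below_tolerance(self, core_model):
        sol = fba(core_model, core_constraints("glucose"))
        assert sol.residual <= 1e-6

    def test_zero_flux_rounding_in_user_output(self):
        sol = fba(linear_chain())
        rounded = sol.rounded()
        assert all(abs(v) >= 1e-5 or v == 0.0 for v in rounded.values())

    def test_relaxing_a_bound_never_decreases_the_optimum(self, core_model):
        base = fba(core_model, core_constraints("glucose")).objective_value
        relaxed = apply_constraints(core_model, core_constraints("glucose"))
        relaxed.reactions["EX_glc"].bounds = (-2.0, -1.0)
        assert fba(relaxed).objective_value >= base - TOL


class TestFva:
    def test_symmetric_diamond_spans_full_range(self):
        ranges = fva(diamond(), gamma=1.0)
        for rid in ("R2a", "R2b"):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-7)
            assert hi == pytest.approx(1.0, abs=1e-7)

    def test_unique_pathway_gives_degenerate_ranges(self):
        ranges = fva(linear_chain(), gamma=1.0)
        for rid, (lo, hi) in ranges.ranges.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-7)

    def test_envelope_contains_the_fba_vertex(self, core_model):
        constraints = core_constraints("glucose")
        sol = fba(core_model, constraints)
        ranges = fva(core_model, constraints, gamma=1.0)
        for rid, (lo, hi) in ranges.ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_ranges_nest_as_gamma_increases(self):
        model = diamond()
        model.reactions["EX_A"].bounds = (-1, 0)  # allow sub-maximal uptake
        loose = fva(model, gamma=0.5)
        tight = fva(model, gamma=1.0)
        for rid in model.reactions:
            assert loose[rid][0] - 1e-7 <= tight[rid][0]
            assert tight[rid][1] <= loose[rid][1] + 1e-7

    def test_gamma_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fva(diamond(), gamma=0.0)

    def test_infeasible_base_problem_propagates(self):
        with pytest.raises(InfeasibleProblemError):
            fva(linear_chain(internal_cap=0.4), gamma=1.0)


class TestApplyConstraints:
    def test_measured_uptake_is_an_equality(self, core_model):
        out = apply_constraints(core_model, ConstraintSet(uptake={"EX_glc": 0.99}))
        assert out.reactions["EX_glc"].bounds == (-0.99, -0.99)
        # original untouched
        assert core_model.reactions["EX_glc"].bounds == (-10.0, 1000.0)

    def test_secretion_is_a_floor(self, core_model):
        out = apply_constraints(
            core_model, ConstraintSet(secretion={"EX_etoh": 0.31}))
        assert out.reactions["EX_etoh"].bounds == (0.31, 1000.0)

    def test_empty_constraint_set_changes_nothing(self, core_model):
        out = apply_constraints(core_model, ConstraintSet())
        assert {r.id: r.bounds for r in out.reactions.values()} == \
            {r.id: r.bounds for r in core_model.reactions.values()}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_fba_matches_dense_oracle_on_random_networks(self, seed):
        model, _ = generate_random_network(FixtureSpec(
            seed=seed, n_linear_pathways=2, n_parallel_pathways=1,
            n_isoenzyme_pairs=1))
        ours = fba(model)
        _, z, _ = dense_lp(model, "BIOMASS", "max")
        assert ours.objective_value == pytest.approx(z, abs=TOL)

    @pytest.mark.parametrize("seed", range(4))
    def test_fva_matches_per_reaction_lp_pairs(self, seed):
        model, _ = generate_random_network(FixtureSpec(
            seed=seed, n_linear_pathways=1, n_parallel_pathways=1,
            n_isoenzyme_pairs=1))
        assert len(model.reactions) <= 15
        ours = fva(model, gamma=1.0)
        theirs = dense_fva(model, "BIOMASS", gamma=1.0)
        for rid in model.reactions:
            assert ours[rid][0] == pytest.approx(theirs[rid][0], abs=TOL)
            assert ours[rid][1] == pytest.approx(theirs[rid][1], abs=TOL)

    def test_core_fixture_fba_matches_oracle(self, core_model):
        constrained = apply_constraints(core_model, core_constraints("glucose"))
        ours = fba(constrained)
        _, z, _ = dense_lp(constrained, constrained.objective_id, "max")
        assert ours.objective_value == pytest.approx(z, abs=TOL)


def test_core_fixture_fba_agrees_with_cobra(core_model, tmp_path):
    """Independent cross-check through an external FBA implementation."""
    import cobra

    from bofsens.io_sbml import write_sbml

    path = tmp_path / "core.xml"
    write_sbml(core_model, path)
    cobra_model = cobra.io.read_sbml_model(str(path))
    expected = fba(core_model).objective_value
    assert cobra_model.optimize().objective_value == pytest.approx(
        expected, abs=1e-5)
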