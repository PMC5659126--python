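"""FSEOF scanning, knockout ranking, robustness classification."""

import pytest

from bofsens.lp import InfeasibleProblemError
from bofsens.model import set_active_biomass
from bofsens.synthetic import core_constraints
from bofsens.targets import (
    KnockoutRanking,
    classify_target_robustness,
    fseof,
    knockout_rank,
    one_to_one_genes,
)


@pytest.fixture()
def fseof_result(core):
    model, _, _ = core
    return fseof(model, core_constraints("oxygen_limited"), "EX_hsod")


class TestFseof:
    def test_product_pathway_reactions_are_candidates(self, fseof_result):
        # product flux must route through synthesis, export, and exchange
        assert {"R_hsod", "T_hsod", "EX_hsod"} <= set(
            fseof_result.candidate_reactions)

    def test_candidate_trajectories_are_monotone(self, fseof_result):
        tol = 1e-6
        for rid in fseof_result.candidate_reactions:
            traj = [abs(v) for v in fseof_result.trajectories[rid]]
            assert all(b >= a - tol for a, b in zip(traj, traj[1:]))
            assert traj[-1] - traj[0] > tol

    def test_enforced_levels_strictly_increase(self, fseof_result):
        levels = fseof_result.enforced_levels
        assert all(b > a for a, b in zip(levels, levels[1:]))

    def test_top_level_reaches_max_fraction_of_potential(self, core):
        model, _, _ = core
        from bofsens.lp import fba
        constraints = core_constraints("oxygen_limited")
        res = fseof(model, constraints, "EX_hsod", max_fraction=0.9)
        from bofsens.lp import apply_constraints
        vmax = fba(apply_constraints(model, constraints),
                   objective="EX_hsod").objective_value
        assert res.enforced_levels[-1] == pytest.approx(0.9 * vmax, rel=1e-6)

    def test_isoenzyme_reaction_excluded_from_gene_candidates(self, fseof_result):
        # the export step is OR-catalysed; it rises but contributes no gene
        assert fseof_result.exclusion_log["T_hsod"].startswith("isoenzyme")
        for gene in ("g_sec1", "g_sec2"):
            assert gene not in fseof_result.candidate_genes

    def test_gene_candidates_restricted_to_one_to_one_mappings(
            self, core, fseof_result):
        model, _, _ = core
        one2one = one_to_one_genes(model)
        assert set(fseof_result.candidate_genes) <= set(one2one)

    def test_no_enforcement_means_no_candidates(self, core):
        model, _, _ = core
        res = fseof(model, core_constraints("oxygen_limited"), "EX_hsod",
                    steps=1, max_fraction=1e-9)
        assert res.candidate_reactions == []

    def test_unproducible_product_is_an_error(self, core):
        model, _, _ = core
        model.reactions["R_hsod"].bounds = (0.0, 0.0)
        with pytest.raises(InfeasibleProblemError, match="not producible"):
            fseof(model, core_constraints("oxygen_limited"), "EX_hsod")

    def test_unknown_product_is_a_key_error(self, core):
        model, _, _ = core
        with pytest.raises(KeyError):
            fseof(model, None, "EX_unobtainium")


class TestKnockoutRank:
    def test_competing_fermentation_branch_ranks_first(self, core):
        """With oxygen fixed, deleting the ethanol branch leaves arabitol
        (capacity-capped) and the product as the only overflow routes, so
        the mutant is forced to secrete product."""
        model, _, _ = core
        ranking = knockout_rank(
            model, core_constraints("oxygen_limited"), "EX_hsod")
        genes = ranking.genes()
        assert genes[0] == "g_adh1"
        assert ranking.ranking[0][1] > 0.0

    def test_lethal_and_slow_mutants_are_excluded(self, core):
        model, _, _ = core
        ranking = knockout_rank(
            model, core_constraints("oxygen_limited"), "EX_hsod")
        assert "g_glk1" in ranking.excluded  # no glucose entry, no growth

    def test_ranking_is_deterministic(self, core):
        model, _, _ = core
        constraints = core_constraints("oxygen_limited")
        a = knockout_rank(model, constraints, "EX_hsod")
        b = knockout_rank(model, constraints, "EX_hsod")
        assert a.ranking == b.ranking

    def test_empty_candidate_pool_gives_empty_ranking(self, core):
        model, _, _ = core
        from bofsens.gpr import EMPTY_GPR
        for rxn in model.reactions.values():
            rxn.gpr = EMPTY_GPR
        ranking = knockout_rank(
            model, core_constraints("oxygen_limited"), "EX_hsod")
        assert ranking.ranking == [] and ranking.genes() == []


class TestRobustness:
    def test_identical_sets_all_robust(self):
        res = classify_target_robustness(
            {"c1": ["a", "b"], "c2": ["a", "b"]})
        assert res.robust == {"a", "b"} and res.conditional == set()

    def test_set_algebra_partition(self):
        res = classify_target_robustness({"c1": ["a", "b"], "c2": ["a", "c"]})
        assert res.robust == {"a"}
        assert res.conditional == {"b", "c"}
        assert res.all_candidates == {"a", "b", "c"}

    def test_robust_subset_of_every_composition(self, core):
        model, comps, _ = core
        constraints = core_constraints("oxygen_limited")
        sets = {}
        for comp in comps:
            set_active_biomass(model, comp.id)
            sets[comp.id] = fseof(model, constraints, "EX_hsod").candidate_genes
        res = classify_target_robustness(sets)
        for genes in sets.values():
            assert res.robust <= set(genes)
        # brute-force set-algebra oracle
        union, inter = set(), None
        for genes in sets.values():
            union |= set(genes)
            inter = set(genes) if inter is None else inter & set(genes)
        assert res.robust == inter
        assert res.conditional == union - inter

    def test_rank_instability_reported(self):
        r1 = KnockoutRanking(product_id="p", ranking=[
            ("a", 3.0, 1.0), ("b", 2.0, 1.0), ("c", 1.0, 1.0)])
        r2 = KnockoutRanking(product_id="p", ranking=[
            ("b", 3.0, 1.0), ("c", 2.0, 1.0), ("a", 1.0, 1.0)])
        res = classify_target_robustness(
            {"c1": r1, "c2": r2}, max_rank_displacement=1)
        assert "a" in res.rank_unstable
        assert res.rank_unstable["a"] == (1, 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_target_robustness({})
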