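"""Sampling, Mann-Whitney/fold-change significance, correlations, scans."""

import math

import numpy as np
import pandas as pd
import pytest

from bofsens.lp import FluxRange
from bofsens.sensitivity import (
    biomass_scan,
    correlation_matrix,
    fold_change,
    mann_whitney_u,
    pairwise_significance,
    sample_flux_distribution,
    sample_size_stability,
    significance_scan,
)
from bofsens.synthetic import CONTRAST_PAIR, DUPLICATE_PAIR, core_constraints


def franges(**ranges):
    return FluxRange(ranges={k: tuple(v) for k, v in ranges.items()})


class TestSampling:
    def test_degenerate_range_yields_constant_samples(self):
        samples = sample_flux_distribution(franges(r=(0.0, 0.0)), n=100, seed=0)
        assert np.all(samples["r"] == 0.0)

    def test_samples_stay_within_bounds(self):
        rng = franges(a=(-2.0, -1.0), b=(0.5, 3.5))
        samples = sample_flux_distribution(rng, n=500, seed=3)
        for rid, (lo, hi) in rng.ranges.items():
            assert samples[rid].min() >= lo
            assert samples[rid].max() <= hi

    def test_uniform_mean_concentrates(self):
        samples = sample_flux_distribution(franges(r=(0.0, 1.0)), n=10000, seed=5)
        assert abs(samples["r"].mean() - 0.5) < 0.02

    def test_reproducible_and_order_invariant(self):
        a = sample_flux_distribution(
            franges(x=(0, 1), y=(2, 3)), n=50, seed=9, label="c1")
        b = sample_flux_distribution(
            franges(y=(2, 3), x=(0, 1)), n=50, seed=9, label="c1")
        assert np.array_equal(a["x"], b["x"])
        assert np.array_equal(a["y"], b["y"])

    def test_different_conditions_get_independent_streams(self):
        a = sample_flux_distribution(franges(x=(0, 1)), n=50, seed=9, label="c1")
        b = sample_flux_distribution(franges(x=(0, 1)), n=50, seed=9, label="c2")
        assert not np.array_equal(a["x"], b["x"])

    def test_sample_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            sample_flux_distribution(franges(r=(0, 1)), n=1, seed=0)


class TestMannWhitney:
    def test_small_disjoint_samples_exact_p(self):
        # U = 0 for {1,2,3} vs {4,5,6}; exact two-sided p = 2/C(6,3) = 0.1
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_samples_give_p_one(self):
        assert mann_whitney_u([2.0] * 10, [2.0] * 10) == 1.0

    def test_identical_vectors_not_significant(self):
        x = np.linspace(0, 1, 100)
        assert mann_whitney_u(x, x) >= 0.99

    def test_agrees_with_scipy_on_large_samples(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 200), rng.normal(0.5, 1, 200)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert mann_whitney_u(x, y) == pytest.approx(expected)


class TestFoldChange:
    def test_both_zero_means_no_change(self):
        assert fold_change(0.0, 0.0) == 1.0

    def test_single_zero_is_infinite(self):
        assert math.isinf(fold_change(0.0, 1.2))

    def test_always_at_least_one_and_symmetric(self):
        assert fold_change(2.0, 8.0) == fold_change(8.0, 2.0) == 4.0
        assert fold_change(-2.0, 4.0) == 2.0

    def test_scale_invariance(self):
        for c in (0.1, 3.0, 1e4):
            assert fold_change(1.5 * c, 0.5 * c) == pytest.approx(3.0)


class TestPairwiseSignificance:
    def test_identical_sample_vectors_not_significant(self):
        x = np.linspace(0.1, 1.0, 100)
        recs = pairwise_significance({"r": x}, {"r": x.copy()})
        assert recs[0].fold_change == 1.0
        assert not recs[0].significant

    def test_zero_versus_clearly_nonzero_flux(self):
        rng = np.random.default_rng(1)
        recs = pairwise_significance(
            {"r": np.zeros(100)}, {"r": rng.uniform(0.5, 1.5, 100)})
        assert math.isinf(recs[0].fold_change)
        assert recs[0].significant

    def test_sub_tolerance_fluxes_count_as_zero(self):
        recs = pairwise_significance(
            {"r": np.full(100, 1e-6)}, {"r": np.full(100, 9e-6)})
        assert recs[0].mean_i == 0.0 and recs[0].mean_j == 0.0
        assert recs[0].fold_change == 1.0

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError):
            pairwise_significance({"a": np.zeros(5)}, {"b": np.zeros(5)})

    def test_filter_is_monotone_in_alpha_and_fc(self):
        rng = np.random.default_rng(7)
        si = {f"r{i}": rng.uniform(0, 1, 100) for i in range(20)}
        sj = {f"r{i}": rng.uniform(0, 2.5, 100) for i in range(20)}

        def sig(alpha, fc):
            return {
                r.reaction_id
                for r in pairwise_significance(si, sj, alpha=alpha,
                                               fc_threshold=fc)
                if r.significant
            }

        assert sig(0.001, 2) <= sig(0.01, 2)
        assert sig(0.01, 3) <= sig(0.01, 2)

    def test_significance_symmetric_in_pair_order(self):
        rng = np.random.default_rng(3)
        si = {f"r{i}": rng.uniform(0, 1, 60) for i in range(10)}
        sj = {f"r{i}": rng.uniform(1, 3, 60) for i in range(10)}
        ab = {r.reaction_id for r in pairwise_significance(si, sj)
              if r.significant}
        ba = {r.reaction_id for r in pairwise_significance(sj, si)
              if r.significant}
        assert ab == ba


class TestCorrelation:
    def test_duplicated_vector_fully_correlated(self):
        v = [1.0, 2.0, 3.0, 4.0]
        m = correlation_matrix({"a": v, "b": list(v)})
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_vector_anticorrelated(self):
        v = np.array([1.0, 2.0, 3.0])
        m = correlation_matrix({"a": v, "b": -v})
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(11)
        vecs = {f"c{i}": rng.normal(size=10) for i in range(3)}
        m = correlation_matrix(vecs)
        for a in vecs:
            for b in vecs:
                x, y = np.asarray(vecs[a]), np.asarray(vecs[b])
                r = (((x - x.mean()) * (y - y.mean())).sum()
                     / np.sqrt(((x - x.mean()) ** 2).sum()
                               * ((y - y.mean()) ** 2).sum()))
                assert m.loc[a, b] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_vector_reported_missing_not_zero(self):
        m = correlation_matrix({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        assert np.isnan(m.loc["a", "b"])
        assert m.loc["a", "a"] == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix({"a": [1, 2], "b": [1, 2, 3]})


class TestConditionScans:
    def test_duplicated_composition_predicts_identically(self, core):
        model, comps, _ = core
        report = biomass_scan(
            model, comps, core_constraints("met_gly"), co2_exchange="EX_co2")
        preds = report.predictions.set_index("composition")
        a, b = DUPLICATE_PAIR
        assert preds.loc[a, "growth"] == pytest.approx(
            preds.loc[b, "growth"], abs=1e-9)
        assert preds.loc[a, "cer"] == pytest.approx(
            preds.loc[b, "cer"], abs=1e-9)

    def test_percent_errors_and_correlation_shape(self, core):
        model, comps, _ = core
        report = biomass_scan(
            model, comps, core_constraints("met_gly"), co2_exchange="EX_co2",
            experimental={"growth": 0.05, "cer": 4.3})
        assert report.infeasible == []
        assert (report.predictions["growth_pct_error"] >= 0).all()
        corr = report.flux_correlation
        assert corr.shape == (12, 12)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_raising_gam_alone_strictly_lowers_growth(self, core):
        """ATP cost of growth is monotone: more maintenance ATP per gram
        of biomass can only reduce the attainable growth rate."""
        from bofsens.biomass import register_compositions
        from bofsens.lp import fba
        from bofsens.model import set_active_biomass
        from bofsens.synthetic import CORE_MONOMER_TABLE
        model, comps, _ = core
        base = comps[0]
        high_gam = type(base)(
            id="high_gam", macro_fractions=dict(base.macro_fractions),
            gam=base.gam + 20.0,
            protein_profile=dict(base.protein_profile),
            carb_profile=dict(base.carb_profile),
            lipid_profile=dict(base.lipid_profile),
            rna_profile=dict(base.rna_profile),
            dna_profile=dict(base.dna_profile))
        register_compositions(model, [high_gam],
                              monomer_table=CORE_MONOMER_TABLE)
        constraints = core_constraints("glucose")
        set_active_biomass(model, base.id)
        low = fba(model, constraints).objective_value
        set_active_biomass(model, "high_gam")
        high = fba(model, constraints).objective_value
        assert high < low

    def test_significance_scan_over_all_pairs(self, met_gly_ranges):
        scan = significance_scan(met_gly_ranges, n=100, seed=0)
        assert scan.significant_reactions(pair=DUPLICATE_PAIR) == set()
        assert scan.significant_reactions(pair=CONTRAST_PAIR)
        # biomass reactions themselves are never compared
        assert not any(r.reaction_id.startswith("BIOMASS_")
                       for r in scan.records)

    def test_stability_report_shapes(self, met_gly_ranges):
        pair_ranges = {c: met_gly_ranges[c] for c in CONTRAST_PAIR}
        report = sample_size_stability(
            pair_ranges, sizes=(50, 100), seed=0)
        assert set(report.reaction_sets) == {50, 100}
        assert report.pairwise_reaction_overlap.shape == (2, 2)
        assert report.reaction_overlap_pct == pytest.approx(100.0)
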