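"""Growth-curve fitting, fitness, genetic-interaction scoring and enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oristress.core import ValidationError
from oristress.qfa import (
    ComplexCatalog,
    FitnessRecord,
    GrowthCurve,
    aggregate_fitness,
    classify_hits,
    complex_enrichment,
    compute_fitness,
    compute_gis,
    cross_screen_compare,
    fit_growth_curve,
    fitness_table,
    population_model,
)
from oristress.synthetic import logistic_density, simulate_growth_curves

from oracles import hypergeom_upper_tail_by_enumeration


def curve_from_params(K, r, g0, t=None, strain="s", gene="g", background="control",
                      replicate=1):
    if t is None:
        t = np.linspace(0.0, 5.0, 30)
    return GrowthCurve(strain, gene, background, replicate, t,
                       logistic_density(t, K, r, g0))


class TestGrowthCurveValidation:
    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            GrowthCurve("s", "g", "control", 1, [0, 1, 2], [1, 2, 3])

    def test_nonincreasing_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            GrowthCurve("s", "g", "control", 1, [0, 1, 1, 2], [1, 2, 3, 4])

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValidationError):
            GrowthCurve("s", "g", "control", 1, [0, 1, 2, 3], [1, 0, 3, 4])


class TestFitGrowthCurve:
    def test_noiseless_parameters_recovered_to_machine_tolerance(self):
        K, r, g0 = 1.0, 4.0, 1.0 / 128.0
        fit = fit_growth_curve(curve_from_params(K, r, g0))
        assert fit.converged
        assert fit.K == pytest.approx(K, rel=1e-6)
        assert fit.r == pytest.approx(r, rel=1e-6)
        assert fit.g0 == pytest.approx(g0, rel=1e-6)

    def test_recovery_across_parameter_grid(self):
        for K, r, g0 in [(0.8, 2.0, 0.01), (1.2, 6.0, 0.02), (1.0, 1.0, 1 / 64)]:
            fit = fit_growth_curve(curve_from_params(K, r, g0))
            assert fit.converged
            assert fit.K == pytest.approx(K, rel=1e-5)
            assert fit.r == pytest.approx(r, rel=1e-5)

    def test_dead_strain_not_converged(self):
        t = np.linspace(0.0, 5.0, 20)
        dens = np.full(20, 1.0 / 128.0)
        fit = fit_growth_curve(GrowthCurve("dead", "g", "query", 1, t, dens))
        assert not fit.converged
        assert compute_fitness(fit) == (0.0, 0.0, 0.0)


class TestComputeFitness:
    def test_doubling_potential_from_capacity_ratio(self):
        # K/g0 = 1024 means exactly 10 doublings
        fit = fit_growth_curve(curve_from_params(1.0, 4.0, 1.0 / 1024.0))
        mdp, mdr, F = compute_fitness(fit)
        assert mdp == pytest.approx(10.0, rel=1e-6)
        assert mdr == pytest.approx((4.0 / np.log(2)) * (1 - 1 / 1024), rel=1e-6)
        assert F == pytest.approx(mdp * mdr, rel=1e-12)

    def test_fitness_scales_linearly_with_rate(self):
        f1 = compute_fitness(fit_growth_curve(curve_from_params(1.0, 2.0, 0.01)))
        f2 = compute_fitness(fit_growth_curve(curve_from_params(1.0, 4.0, 0.01)))
        assert f2[2] == pytest.approx(2.0 * f1[2], rel=1e-4)


class TestFitnessAggregation:
    def test_fitness_table_fits_each_replicate(self):
        curves, _ = simulate_growth_curves(
            [("gA", "control", 0.0), ("gA", "query", 0.0)], reps=3, seed=0,
            timepoints=np.linspace(0, 5, 15),
        )
        fits = fitness_table(curves)
        assert len(fits) == 6
        assert {"gene", "background", "replicate", "K", "r", "g0", "MDP", "MDR", "F"} \
            <= set(fits.columns)

    def test_missing_background_excluded_with_warning(self):
        fits = pd.DataFrame(
            {
                "gene": ["gA", "gA", "gB", "gB", "gB", "gB"],
                "background": ["control", "control", "control", "control",
                               "query", "query"],
                "replicate": [1, 2, 1, 2, 1, 2],
                "F": [20.0, 21.0, 19.0, 20.0, 15.0, 16.0],
            }
        )
        with pytest.warns(UserWarning):
            records = aggregate_fitness(fits)
        assert {r.gene for r in records} == {"gB"}

    def test_record_moments(self):
        r = FitnessRecord("g", "control", [10.0, 12.0, 14.0])
        assert r.mean_F == 12.0
        assert r.sd_F == pytest.approx(2.0)


def _panel_records(n_genes=40, a=2.0, b=0.8, outliers=(), seed=0, noise=0.0):
    """Fitness records on an exact population line, with optional outliers."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        gene = f"g{i:03d}"
        fc = 10.0 + (i % 10)
        fq = a + b * fc + outliers_dict(outliers).get(gene, 0.0)
        noise_c = rng.normal(0, noise, 3) if noise else np.zeros(3)
        noise_q = rng.normal(0, noise, 3) if noise else np.zeros(3)
        records.append(FitnessRecord(gene, "control", (fc + noise_c).tolist()))
        records.append(FitnessRecord(gene, "query", (fq + noise_q).tolist()))
    return records


def outliers_dict(outliers):
    return dict(outliers)


class TestPopulationModelAndGIS:
    def test_exact_line_recovered(self):
        model = population_model(_panel_records(a=2.0, b=0.8))
        assert model.intercept == pytest.approx(2.0, abs=1e-6)
        assert model.slope == pytest.approx(0.8, abs=1e-6)
        assert model.n_genes == 40

    def test_robust_line_ignores_strong_interactions(self):
        # four severe enhancers should barely move the Huber line
        out = [("g001", -8.0), ("g011", -8.0), ("g021", -8.0), ("g031", -8.0)]
        model = population_model(_panel_records(a=2.0, b=0.8, outliers=out, noise=0.05))
        assert model.intercept == pytest.approx(2.0, abs=0.2)
        assert model.slope == pytest.approx(0.8, abs=0.02)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            population_model(_panel_records(n_genes=5))

    def test_gis_zero_on_the_line(self):
        records = _panel_records(a=2.0, b=0.8)
        model = population_model(records)
        for rec in compute_gis(records, model):
            assert rec.gis == pytest.approx(0.0, abs=1e-6)

    def test_gis_measures_departure_from_line(self):
        records = _panel_records(a=2.0, b=0.8, outliers=[("g005", -3.0)], noise=0.05)
        model = population_model(records)
        gis = {r.gene: r for r in compute_gis(records, model)}
        assert gis["g005"].gis == pytest.approx(-3.0, abs=0.3)
        assert gis["g005"].q < 0.05

    def test_single_replicate_gene_gets_missing_p(self):
        records = _panel_records()
        records.append(FitnessRecord("gX", "control", [10.0]))
        records.append(FitnessRecord("gX", "query", [10.0]))
        model = population_model(records)
        gis = {r.gene: r for r in compute_gis(records, model)}
        assert np.isnan(gis["gX"].p)

    def test_classify_hits_needs_both_significance_and_magnitude(self):
        records = _panel_records(a=2.0, b=0.8, outliers=[("g005", -3.0), ("g015", 3.0)],
                                 noise=0.05)
        model = population_model(records)
        gis = compute_gis(records, model)
        enhancers, suppressors = classify_hits(gis, top_fraction=0.25, q_max=0.05)
        assert [r.gene for r in enhancers] == ["g005"]
        assert [r.gene for r in suppressors] == ["g015"]
        by_gene = {r.gene: r.hit_class for r in gis}
        assert by_gene["g005"] == "enhancer"
        assert by_gene["g015"] == "suppressor"
        assert by_gene["g000"] == "neutral"

    def test_classify_hits_top_fraction_validated(self):
        with pytest.raises(ValidationError):
            classify_hits([], top_fraction=0.0)


class TestComplexEnrichment:
    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        members = {"g0", "g1", "g2", "g3"}
        hits = {"g0", "g1", "g2", "g5"}
        catalog = ComplexCatalog({"cohesin": members})
        table = complex_enrichment(hits, set(universe), catalog)
        expected = hypergeom_upper_tail_by_enumeration(universe, members, hits)
        assert table.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_enumeration_property_on_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        universe = [f"g{i}" for i in range(n)]
        members = set(rng.choice(universe, size=int(rng.integers(2, n // 2 + 2)),
                                 replace=False))
        hits = set(rng.choice(universe, size=int(rng.integers(1, n // 2 + 1)),
                              replace=False))
        table = complex_enrichment(hits, set(universe), ComplexCatalog({"c": members}))
        expected = hypergeom_upper_tail_by_enumeration(universe, members, hits)
        assert table.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_small_complexes_skipped(self):
        catalog = ComplexCatalog({"solo": {"g0"}})
        table = complex_enrichment({"g0"}, {"g0", "g1", "g2"}, catalog)
        assert table.empty

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            complex_enrichment({"gZ"}, {"g0"}, ComplexCatalog({"c": {"g0", "g1"}}))


class TestCrossScreenCompare:
    def test_identical_screens_correlate_perfectly(self):
        records = _panel_records(a=2.0, b=0.8, outliers=[("g005", -3.0)], noise=0.05)
        model = population_model(records)
        gis = compute_gis(records, model)
        classify_hits(gis)
        result = cross_screen_compare(gis, gis)
        assert result["spearman_rho"] == pytest.approx(1.0)
        assert result["enhancers"]["jaccard"] == 1.0

    def test_too_few_shared_genes_rejected(self):
        records = _panel_records(n_genes=25)
        model = population_model(records)
        gis = compute_gis(records, model)
        with pytest.raises(ValidationError):
            cross_screen_compare(gis[:10], gis[:10], min_shared=20)
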