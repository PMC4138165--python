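"""The regularized maxent SDM: fitting, evaluation, thresholding, projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from nichedyn import (
    OccurrenceSet,
    SuitabilityMap,
    auc_score,
    compare_binary_ranges,
    evaluate,
    fit_maxent,
    project,
    sample_background,
    sample_occurrences,
    suitability_surface,
    threshold_at_percentile,
)
from nichedyn.maxent import cell_areas_km2
from nichedyn.raster import GridGeometry
from nichedyn.synthetic import (
    VirtualLandscapeSpec,
    default_landscape_pair,
    default_species,
    make_landscape,
)
from tests.conftest import full_box


@pytest.fixture(scope="module")
def sdm_setup():
    """Standard-conditions single-region fit problem."""
    ln, _ = default_landscape_pair(1)
    sp = default_species(1)
    stack = make_landscape(ln)
    suit = suitability_surface(stack, sp)
    occ = sample_occurrences(suit, 500, seed=11)
    bg = sample_background(full_box(stack), stack, 10000, seed=12)
    return stack, bg, occ


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.7], [0.3, 0.2, 0.1]) == 1.0

    def test_rank_formula_equals_trapezoidal_roc_on_toy(self):
        pos = np.array([0.9, 0.8, 0.8, 0.6, 0.4])
        neg = np.array([0.7, 0.5, 0.5, 0.3, 0.1])
        # brute-force ROC: sweep thresholds, integrate TPR over FPR
        thr = np.unique(np.concatenate([pos, neg, [np.inf]]))[::-1]
        tpr = [(pos >= t).mean() for t in thr]
        fpr = [(neg >= t).mean() for t in thr]
        trapezoid = np.trapezoid(tpr, fpr)
        assert auc_score(pos, neg) == pytest.approx(trapezoid)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(5, 40, size=2)
            pos = rng.normal(0.3, 1, n1)
            neg = rng.normal(0.0, 1, n2)
            u, _ = mannwhitneyu(pos, neg, alternative="two-sided")
            assert auc_score(pos, neg) == pytest.approx(u / (n1 * n2))

    # decimally-spaced scores: exp() must not round distinct values into ties
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=20),
           st.lists(st.integers(-50, 50), min_size=3, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, pos, neg):
        pos, neg = np.array(pos) / 10.0, np.array(neg) / 10.0
        a = auc_score(pos, neg)
        assert a == pytest.approx(auc_score(np.exp(pos / 3), np.exp(neg / 3)))
        assert a == pytest.approx(auc_score(3 * pos + 7, 3 * neg + 7))


class TestThreshold:
    def test_decile_toy(self):
        vals = np.arange(0.1, 1.01, 0.1)
        assert threshold_at_percentile(vals, 10) == pytest.approx(0.1)

    def test_constant_scores(self):
        assert threshold_at_percentile([0.42] * 25, 10) == pytest.approx(0.42)

    def test_matches_nearest_rank_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            vals = rng.uniform(size=rng.integers(10, 200))
            srt = np.sort(vals)
            expected = srt[int(np.ceil(0.10 * len(vals))) - 1]
            assert threshold_at_percentile(vals, 10) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            threshold_at_percentile([])


class TestFitMaxent:
    def test_huge_beta_collapses_to_uniform(self, sdm_setup):
        stack, bg, occ = sdm_setup
        model = fit_maxent(stack, bg, occ, beta=1e6)
        assert np.abs(model.lambdas).max() == pytest.approx(0.0, abs=1e-8)
        suit = model.suitability(stack.env_at_points(bg.lon, bg.lat))
        np.testing.assert_allclose(suit, 0.5, atol=1e-6)

    def test_positive_signal_gives_positive_linear_coefficient(self, small_stack):
        v = small_stack.layers["env1"]
        hi = v > np.quantile(v, 0.8)
        rows, cols = np.nonzero(hi)
        pick = np.random.default_rng(3).choice(len(rows), 60, replace=False)
        lon, lat = small_stack.geometry.cell_center(rows[pick], cols[pick])
        occ = OccurrenceSet(records=pd.DataFrame({"lon": lon, "lat": lat}))
        bg = sample_background(full_box(small_stack), small_stack, 2000, seed=14)
        model = fit_maxent(small_stack, bg, occ, beta=1.0)
        idx = model.feature_spec.terms.index(("linear", 0))
        assert model.lambdas[idx] > 0

    def test_objective_agrees_across_random_starts(self, sdm_setup):
        stack, bg, occ = sdm_setup
        base = fit_maxent(stack, bg, occ, beta=1.0)
        rng = np.random.default_rng(0)
        for _ in range(3):
            x0 = rng.normal(scale=5.0, size=base.feature_spec.n_features)
            alt = fit_maxent(stack, bg, occ, beta=1.0, x0=x0)
            assert alt.objective == pytest.approx(base.objective, abs=1e-6)

    def test_stronger_regularization_never_adds_coefficients(self, sdm_setup):
        stack, bg, occ = sdm_setup
        counts = []
        for beta in (0.5, 1.0, 2.0, 4.0):
            m = fit_maxent(stack, bg, occ, beta=beta)
            counts.append(int((np.abs(m.lambdas) > 1e-6).sum()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_too_few_presences_rejected(self, sdm_setup):
        stack, bg, occ = sdm_setup
        tiny = OccurrenceSet(records=occ.records.iloc[:5])
        with pytest.raises(ValueError, match="10"):
            fit_maxent(stack, bg, tiny)


class TestEvaluate:
    def test_gaussian_niche_truth_is_learnable(self, sdm_setup):
        stack, bg, occ = sdm_setup
        ev = evaluate(stack, bg, occ, beta=1.0, n_replicates=10, seed=5)
        assert ev.auc_test >= 0.8
        assert ev.auc_train >= ev.auc_test - 0.05

    def test_no_signal_gives_chance_auc(self, sdm_setup):
        stack, bg, _ = sdm_setup
        flat = SuitabilityMap(
            geometry=stack.geometry,
            values=np.where(stack.nodata_mask, np.nan, 1.0),
            nodata_mask=stack.nodata_mask,
        )
        occ_null = sample_occurrences(flat, 1000, seed=13)
        ev = evaluate(stack, bg, occ_null, beta=1.0, n_replicates=10, seed=6)
        assert abs(ev.auc_test - 0.5) < 0.05

    def test_split_too_small_is_error(self, sdm_setup):
        stack, bg, occ = sdm_setup
        tiny = OccurrenceSet(records=occ.records.iloc[:10])
        with pytest.raises(ValueError, match="test split"):
            evaluate(stack, bg, tiny, train_fraction=0.9, n_replicates=2)


class TestProject:
    def test_identity_projection_reproduces_training_scores(self, sdm_setup):
        stack, bg, occ = sdm_setup
        model = fit_maxent(stack, bg, occ, beta=1.0)
        smap = project(model, stack)
        env = stack.env_table()
        np.testing.assert_allclose(
            smap.values[stack.valid_mask], model.suitability(env), rtol=1e-12
        )

    def test_extrapolation_mask_flags_shifted_target(self, sdm_setup):
        stack, bg, occ = sdm_setup
        model = fit_maxent(stack, bg, occ, beta=1.0)
        from nichedyn.raster import ClimateStack

        shifted = ClimateStack(
            geometry=stack.geometry,
            layers={n: v + 5.0 for n, v in stack.layers.items()},
            nodata_mask=stack.nodata_mask.copy(),
        )
        smap = project(model, shifted)
        assert smap.extrapolation_mask.any()
        identity = project(model, stack)
        # training background spans the stack, so only cells outside the
        # sampled background range are flagged there
        assert identity.extrapolation_mask.mean() < 0.05

    def test_missing_variable_named(self, sdm_setup):
        stack, bg, occ = sdm_setup
        model = fit_maxent(stack, bg, occ, beta=1.0)
        partial = stack.subset(stack.layer_names[:-1])
        with pytest.raises(ValueError, match=stack.layer_names[-1]):
            project(model, partial)


class TestBinaryRanges:
    def _map(self, values, geom):
        return SuitabilityMap(geometry=geom, values=values,
                              nodata_mask=np.zeros(geom.shape, bool))

    def test_equator_one_degree_cell_area(self):
        geom = GridGeometry(origin_lon=0, origin_lat=0.5, cell_size=1.0,
                            n_rows=1, n_cols=1)
        assert cell_areas_km2(geom)[0] == pytest.approx(
            111.320 * 110.574, rel=1e-6
        )

    def test_identity_comparison(self):
        geom = GridGeometry(origin_lon=0, origin_lat=2, cell_size=1.0,
                            n_rows=2, n_cols=2)
        m = self._map(np.array([[0.9, 0.1], [0.8, 0.2]]), geom)
        cmp = compare_binary_ranges(m, m, 0.5, 0.5)
        assert cmp.frac_1_in_2 == 1.0 and cmp.frac_2_in_1 == 1.0
        assert cmp.area_only1_km2 == 0.0 and cmp.area_only2_km2 == 0.0
        assert cmp.area_both_km2 == pytest.approx(cmp.area_map1_km2)

    def test_nested_ranges(self):
        geom = GridGeometry(origin_lon=0, origin_lat=2, cell_size=1.0,
                            n_rows=2, n_cols=2)
        m1 = self._map(np.array([[0.9, 0.0], [0.0, 0.0]]), geom)
        m2 = self._map(np.array([[0.9, 0.9], [0.9, 0.0]]), geom)
        cmp = compare_binary_ranges(m1, m2, 0.5, 0.5)
        assert cmp.frac_1_in_2 == 1.0
        assert cmp.area_map2_km2 > cmp.area_map1_km2
        # the partition covers the union
        union = cmp.area_only1_km2 + cmp.area_only2_km2 + cmp.area_both_km2
        assert union == pytest.approx(
            cmp.area_map1_km2 + cmp.area_map2_km2 - cmp.area_both_km2
        )
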