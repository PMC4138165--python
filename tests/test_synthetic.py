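"""Virtual landscapes, species, occurrence sampling, and scenario pairs."""

import numpy as np
import pytest
from scipy.stats import chisquare

from nichedyn import (
    ScenarioSpec,
    SuitabilityMap,
    VirtualLandscapeSpec,
    VirtualSpeciesSpec,
    default_landscape_pair,
    default_species,
    make_landscape,
    make_scenario_pair,
    sample_occurrences,
    suitability_surface,
)


class TestMakeLandscape:
    def test_deterministic_under_seed(self):
        spec = VirtualLandscapeSpec(region_id="d", n_rows=20, n_cols=20, seed=5)
        a, b = make_landscape(spec), make_landscape(spec)
        for name in a.layers:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.9])
    def test_pairwise_correlation_near_target(self, rho):
        spec = VirtualLandscapeSpec(region_id="c", n_rows=50, n_cols=50,
                                    n_layers=3, spatial_smoothing=5.0,
                                    layer_correlation=rho, seed=1)
        stack = make_landscape(spec)
        x = np.column_stack([v.ravel() for v in stack.layers.values()])
        r = np.corrcoef(x, rowvar=False)
        iu = np.triu_indices(3, 1)
        assert np.all(np.abs(r[iu] - rho) < 0.15)

    def test_no_smoothing_gives_white_noise(self):
        spec = VirtualLandscapeSpec(region_id="w", n_rows=60, n_cols=60,
                                    n_layers=2, spatial_smoothing=0.0,
                                    layer_correlation=0.0, seed=2)
        stack = make_landscape(spec)
        for v in stack.layers.values():
            lag_row = np.corrcoef(v[:-1].ravel(), v[1:].ravel())[0, 1]
            lag_col = np.corrcoef(v[:, :-1].ravel(), v[:, 1:].ravel())[0, 1]
            assert abs(lag_row) < 0.1 and abs(lag_col) < 0.1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            VirtualLandscapeSpec(region_id="x", n_rows=5, n_cols=20)
        with pytest.raises(ValueError):
            VirtualLandscapeSpec(region_id="x", n_layers=1)
        with pytest.raises(ValueError):
            VirtualLandscapeSpec(region_id="x", spatial_smoothing=-1)
        with pytest.raises(ValueError):
            VirtualLandscapeSpec(region_id="x", n_layers=3, layer_correlation=-0.5)


class TestSuitability:
    def test_closed_form(self, small_stack):
        center = tuple(float(v.mean()) for v in small_stack.layers.values())
        sp = VirtualSpeciesSpec(niche_center=center, niche_breadth=(1.0, 1.0, 1.0),
                                max_suitability=0.8)
        suit = suitability_surface(small_stack, sp)
        # a cell whose environment is exactly the center scores max_suitability
        env = np.stack([v for v in small_stack.layers.values()], axis=-1)
        z2 = (((env - np.array(center)) / 1.0) ** 2).sum(axis=-1)
        np.testing.assert_allclose(suit.values, 0.8 * np.exp(-0.5 * z2))

    def test_one_sigma_cell(self):
        from nichedyn.raster import ClimateStack, GridGeometry

        geom = GridGeometry(origin_lon=0, origin_lat=1, cell_size=1, n_rows=1, n_cols=2)
        stack = ClimateStack(geometry=geom, layers={
            "a": np.array([[0.0, 2.0]]), "b": np.array([[5.0, 5.0]])})
        sp = VirtualSpeciesSpec(niche_center=(0.0, 5.0), niche_breadth=(2.0, 1.0))
        suit = suitability_surface(stack, sp)
        assert suit.values[0, 0] == pytest.approx(1.0)
        assert suit.values[0, 1] == pytest.approx(np.exp(-0.5))

    def test_dimension_mismatch_and_mask(self, small_stack):
        sp = VirtualSpeciesSpec(niche_center=(0.0,), niche_breadth=(1.0,))
        with pytest.raises(ValueError, match="dimension"):
            suitability_surface(small_stack, sp)
        all_masked = small_stack.with_mask(np.ones(small_stack.geometry.shape, bool))
        sp3 = default_species(0)
        sp3 = VirtualSpeciesSpec(niche_center=(0, 0, 0), niche_breadth=(1, 1, 1))
        suit = suitability_surface(all_masked, sp3)
        assert np.isnan(suit.values).all()


class TestSampleOccurrences:
    def _map(self, values, geom):
        return SuitabilityMap(geometry=geom, values=values,
                              nodata_mask=~np.isfinite(values))

    def test_single_positive_cell_forced(self, small_stack):
        geom = small_stack.geometry
        vals = np.zeros(geom.shape)
        vals[7, 9] = 1.0
        occ = sample_occurrences(self._map(vals, geom), 1, seed=0)
        lon, lat = geom.cell_center(7, 9)
        assert occ.lon[0] == pytest.approx(lon) and occ.lat[0] == pytest.approx(lat)

    def test_uniform_suitability_uniform_frequencies(self, small_stack):
        geom = small_stack.geometry
        vals = np.ones(geom.shape)
        n = 20000
        occ = sample_occurrences(self._map(vals, geom), n, seed=4, dedup=False)
        row, col = geom.cell_of(occ.lon, occ.lat)
        counts = np.bincount(row * geom.n_cols + col, minlength=geom.n_rows * geom.n_cols)
        stat, p = chisquare(counts)
        assert p > 0.001  # multinomial-noise level, not a real deviation

    def test_deterministic(self, small_stack):
        suit = suitability_surface(small_stack, VirtualSpeciesSpec(
            niche_center=(10.0, 20.0, 30.0), niche_breadth=(2.0, 2.0, 2.0)))
        a = sample_occurrences(suit, 50, seed=6)
        b = sample_occurrences(suit, 50, seed=6)
        np.testing.assert_array_equal(a.lon, b.lon)

    def test_dedup_capacity_error_reports_maximum(self, small_stack):
        geom = small_stack.geometry
        vals = np.zeros(geom.shape)
        vals[0, :5] = 1.0
        with pytest.raises(ValueError, match="5"):
            sample_occurrences(self._map(vals, geom), 6, seed=0)


class TestScenarios:
    def test_conserved_shares_the_species(self):
        ln, li = default_landscape_pair(0, n_rows=40, n_cols=40)
        sp = default_species(0)
        pair = make_scenario_pair(ln, li, sp, ScenarioSpec("conserved"), 50, 50)
        assert pair.species_native == pair.species_invaded

    def test_expanded_shift_applied_exactly(self):
        ln, li = default_landscape_pair(0, n_rows=40, n_cols=40)
        sp = default_species(0)
        shift = (2 * sp.niche_breadth[0], 0.0, 0.0, 0.0)
        pair = make_scenario_pair(ln, li, sp, ScenarioSpec("expanded", shift=shift),
                                  50, 50)
        got = np.array(pair.species_invaded.niche_center) - np.array(sp.niche_center)
        np.testing.assert_allclose(got, shift)

    def test_unfilled_truncates_strictly_inside_native_range(self):
        ln, li = default_landscape_pair(1, n_rows=60, n_cols=60)
        sp = default_species(1)
        pair = make_scenario_pair(
            ln, li, sp, ScenarioSpec("unfilled", truncation_quantile=0.5), 50, 50
        )
        for name in pair.stack_native.layer_names:
            nat = pair.stack_native.layers[name][pair.stack_native.valid_mask]
            inv = pair.stack_invaded.layers[name][pair.stack_invaded.valid_mask]
            assert inv.min() > nat.min() and inv.max() < nat.max()

    def test_scenario_spec_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec("conserved", shift=(1.0,))
        with pytest.raises(ValueError):
            ScenarioSpec("expanded", shift=(0.0,))
        with pytest.raises(ValueError):
            ScenarioSpec("weird")
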