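"""Environmental PCA space and gridded occupancy densities."""

import numpy as np
import pandas as pd
import pytest

from nichedyn import (
    OccurrenceSet,
    build_niche_grid,
    fit_pca,
    sample_background,
    schoener_d,
)
from nichedyn.niche import PcaSpace, project_points
from nichedyn.raster import ClimateStack, GridGeometry
from tests.conftest import full_box, scenario_grids


def two_region_setup(small_stack):
    """Reuse the small landscape as both regions (plain unit-test plumbing)."""
    bg1 = sample_background(full_box(small_stack), small_stack, 800, seed=1)
    bg2 = sample_background(full_box(small_stack), small_stack, 800, seed=2)
    return bg1, bg2


class TestFitPca:
    def test_rank_one_pair_explains_everything_on_axis1(self, small_stack):
        a = small_stack.layers["env1"]
        stack = ClimateStack(geometry=small_stack.geometry,
                             layers={"A": a, "B": 3.0 * a + 1.0})
        bg1, bg2 = two_region_setup(small_stack)
        pca = fit_pca(stack, stack, bg1, bg2)
        assert pca.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, small_stack):
        bg1, bg2 = two_region_setup(small_stack)
        pca = fit_pca(small_stack, small_stack, bg1, bg2)
        assert pca.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(pca.explained_variance_fraction) <= 1e-12)

    def test_loadings_recover_known_rotation(self):
        # two variables built from two orthogonal factors via a known rotation;
        # oracle: leading eigenvector of the correlation matrix (eigh), which
        # is what the standardized PCA's first loading must reproduce
        rng = np.random.default_rng(0)
        theta = 0.6
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        factors = rng.normal(size=(4000, 2)) * [3.0, 1.0]
        data = factors @ rot.T
        geom = GridGeometry(origin_lon=0, origin_lat=1, cell_size=1,
                            n_rows=1, n_cols=4000)
        stack = ClimateStack(geometry=geom, layers={
            "x": data[:, 0].reshape(1, -1), "y": data[:, 1].reshape(1, -1)})
        lon, lat = geom.cell_center(np.zeros(4000, int), np.arange(4000))
        from nichedyn.geo import BackgroundRegion
        bg = BackgroundRegion(west=0, east=4000, south=0, north=1,
                              points=np.column_stack([lon, lat]))
        pca = fit_pca(stack, stack, bg, bg)
        corr = np.corrcoef(np.vstack([data, data]), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        expected = np.abs(evecs[:, np.argmax(evals)])
        np.testing.assert_allclose(np.abs(pca.loadings[:, 0]), expected, atol=1e-8)
        assert pca.explained_variance_fraction[0] == pytest.approx(
            evals.max() / evals.sum())

    def test_zero_variance_variable_named_in_error(self, small_stack):
        stack = ClimateStack(geometry=small_stack.geometry,
                             layers={"flat": np.ones(small_stack.geometry.shape),
                                     "a": small_stack.layers["env1"]})
        bg1, bg2 = two_region_setup(small_stack)
        with pytest.raises(ValueError, match="flat"):
            fit_pca(stack, stack, bg1, bg2)


class TestProject:
    def test_background_mean_maps_to_origin(self, small_stack):
        bg1, bg2 = two_region_setup(small_stack)
        pca = fit_pca(small_stack, small_stack, bg1, bg2)
        mean_env = np.vstack([
            small_stack.env_at_points(bg1.lon, bg1.lat),
            small_stack.env_at_points(bg2.lon, bg2.lat),
        ]).mean(axis=0)
        np.testing.assert_allclose(pca.transform(mean_env[None, :]), 0.0, atol=1e-9)

    def test_projection_is_affine(self, small_stack):
        bg1, bg2 = two_region_setup(small_stack)
        pca = fit_pca(small_stack, small_stack, bg1, bg2)
        rng = np.random.default_rng(1)
        a, b, c = rng.normal(size=(3, small_stack.n_layers)) * 2 + 20
        diff_ab = pca.transform(a[None]) - pca.transform(b[None])
        diff_shifted = pca.transform((a + c)[None]) - pca.transform((b + c)[None])
        np.testing.assert_allclose(diff_ab, diff_shifted, atol=1e-9)

    def test_matches_hand_computed_toy(self):
        means = np.array([1.0, 2.0])
        scales = np.array([2.0, 4.0])
        loadings = np.array([[1.0, 0.0], [0.0, 1.0]])
        pca = PcaSpace(variable_names=["a", "b"], means=means, scales=scales,
                       loadings=loadings,
                       explained_variance_fraction=np.array([0.7, 0.3]),
                       axis1_range=(-3, 3), axis2_range=(-3, 3))
        env = np.array([[3.0, 10.0], [1.0, 2.0], [-1.0, -2.0]])
        expected = (env - means) / scales
        np.testing.assert_allclose(pca.transform(env), expected)

    def test_nodata_point_raises(self, small_stack):
        bg1, bg2 = two_region_setup(small_stack)
        pca = fit_pca(small_stack, small_stack, bg1, bg2)
        masked = small_stack.with_mask(
            np.ones(small_stack.geometry.shape, bool))
        with pytest.raises(ValueError):
            project_points(pca, masked, [bg1.lon[0]], [bg1.lat[0]])


class TestBuildNicheGrid:
    def test_grid_contract_invariants(self):
        gn, gi = scenario_grids("conserved", 1, R=50)
        for g in (gn, gi):
            assert (g.z >= 0).all() and (g.o >= 0).all() and (g.e >= 0).all()
            assert np.all(g.z[~g.envelope_100] == 0)
            assert np.all(g.envelope_75 <= g.envelope_100)
            assert g.p.sum() == pytest.approx(1.0)
        assert gn.same_frame(gi)

    def test_uniform_occupancy_is_flat_on_the_envelope(self):
        # a background uniform in environment space (coordinate-ramp layers)
        # with occurrences drawn uniformly over it: corrected occupancy is
        # near-constant across the envelope
        geom = GridGeometry(origin_lon=0.0, origin_lat=30.0, cell_size=1.0,
                            n_rows=30, n_cols=30)
        cols_grid, rows_grid = np.meshgrid(np.arange(30.0), np.arange(30.0))
        stack = ClimateStack(geometry=geom,
                             layers={"x": cols_grid, "y": 30.0 - rows_grid})
        bg = sample_background(full_box(stack), stack, 10000, seed=3)
        rng = np.random.default_rng(8)
        lon, lat = geom.cell_center(rng.integers(0, 30, 1000),
                                    rng.integers(0, 30, 1000))
        occ = OccurrenceSet(records=pd.DataFrame({"lon": lon, "lat": lat}))
        pca = fit_pca(stack, stack, bg, bg)
        grid = build_niche_grid(pca, stack, bg, occ, R=100)
        vals = grid.z[grid.envelope_75]
        assert vals.std() / vals.mean() < 0.25

    def test_tight_cluster_peaks_at_cluster_location(self, small_stack):
        bg = sample_background(full_box(small_stack), small_stack, 5000, seed=4)
        lon, lat = small_stack.geometry.cell_center(
            np.full(30, 12), np.full(30, 17))
        occ = OccurrenceSet(records=pd.DataFrame({
            "lon": lon + np.linspace(0, 1e-6, 30), "lat": lat}))
        pca = fit_pca(small_stack, small_stack, bg, bg)
        grid = build_niche_grid(pca, small_stack, bg, occ, R=60)
        score = project_points(pca, small_stack, [lon[0]], [lat[0]])[0]
        i = int((score[0] - grid.axis1_range[0])
                / (grid.axis1_range[1] - grid.axis1_range[0]) * grid.R)
        j = int((score[1] - grid.axis2_range[0])
                / (grid.axis2_range[1] - grid.axis2_range[0]) * grid.R)
        imax, jmax = np.unravel_index(np.argmax(grid.z), grid.z.shape)
        assert abs(imax - i) <= 2 and abs(jmax - j) <= 2

    def test_too_few_occurrences_rejected(self, small_stack):
        bg = sample_background(full_box(small_stack), small_stack, 500, seed=5)
        lon, lat = small_stack.geometry.cell_center([1, 2], [1, 2])
        occ = OccurrenceSet(records=pd.DataFrame({"lon": lon, "lat": lat}))
        pca = fit_pca(small_stack, small_stack, bg, bg)
        with pytest.raises(ValueError, match="at least 5"):
            build_niche_grid(pca, small_stack, bg, occ)

    def test_overlap_stable_under_grid_resolution(self):
        d_100 = schoener_d(*scenario_grids("conserved", 1, R=100))
        d_200 = schoener_d(*scenario_grids("conserved", 1, R=200))
        assert abs(d_100 - d_200) < 0.05
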