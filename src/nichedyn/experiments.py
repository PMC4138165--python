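"""Canned validation experiments on the synthetic study conditions.

These assemble the standard virtual-species setups used to validate the
estimators: the three niche-dynamics scenarios under the default study
conditions, and the reciprocal-projection asymmetry experiment in which the
invading population sits behind a low-gradient filter. They are ordinary
package code — the same entry points back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from ._seeds import derive_seed
from .geo import sample_background
from .maxent import (
    compare_binary_ranges,
    fit_maxent,
    project,
    threshold_at_percentile,
)
from .niche import NicheGrid, build_niche_grid, fit_pca
from .profiles import compare_profiles, occupancy_profile
from .raster import ClimateStack
from .synthetic import (
    ScenarioSpec,
    default_landscape_pair,
    default_species,
    make_landscape,
    make_scenario_pair,
    sample_occurrences,
    suitability_surface,
    truncated_occupancy_surface,
)

__all__ = ["full_box", "scenario_niche_grids", "asymmetry_experiment"]


def full_box(stack: ClimateStack) -> tuple[float, float, float, float]:
    """(west, east, south, north) box spanning a stack's whole grid."""
    west, south, east, north = stack.geometry.bounds
    return (west, east, south, north)


def scenario_niche_grids(
    kind: str,
    seed: int,
    R: int = 100,
    n_occurrences: int = 1000,
    n_background: int = 10000,
    shift_breadths: float = 2.0,
    truncation_quantile: float = 0.5,
) -> tuple[NicheGrid, NicheGrid]:
    """Native and invaded niche grids for one scenario under the standard
    study conditions (160x160 landscapes, default species, shared PCA)."""
    ln, li = default_landscape_pair(seed)
    sp = default_species(seed)
    breadth = sp.niche_breadth[0]
    scen = {
        "conserved": ScenarioSpec("conserved"),
        "unfilled": ScenarioSpec("unfilled", truncation_quantile=truncation_quantile),
        "expanded": ScenarioSpec(
            "expanded", shift=(shift_breadths * breadth, 0.0, 0.0, 0.0)
        ),
    }[kind]
    pair = make_scenario_pair(ln, li, sp, scen, n_occurrences, n_occurrences)
    bg_nat = sample_background(
        full_box(pair.stack_native), pair.stack_native, n_background,
        seed * 100 + 1,
    )
    bg_inv = sample_background(
        full_box(pair.stack_invaded), pair.stack_invaded, n_background,
        seed * 100 + 2,
    )
    pca = fit_pca(pair.stack_native, pair.stack_invaded, bg_nat, bg_inv)
    grid_nat = build_niche_grid(pca, pair.stack_native, bg_nat, pair.occ_native, R=R)
    grid_inv = build_niche_grid(pca, pair.stack_invaded, bg_inv, pair.occ_invaded, R=R)
    return grid_nat, grid_inv


def asymmetry_experiment(
    seed: int,
    n_presences: int = 400,
    n_background: int = 3000,
    beta: float = 1.0,
    percentile: float = 10.0,
) -> dict:
    """Reciprocal-projection asymmetry on a low-altitude-filtered invasion.

    The native population occupies its full Gaussian niche; the invading one
    only cells below the median of one gradient layer and with at least 25%
    of maximal suitability. Both maxent models are projected onto the full
    invaded landscape and their thresholded ranges, areas, and gradient
    profiles compared. Under niche conservatism with incomplete filling the
    native-trained range should contain the invaded-trained one, cover more
    area, and sit higher on the gradient.
    """
    ln, li = default_landscape_pair(seed)
    sp = default_species(seed)
    st_nat = make_landscape(ln)
    st_inv = make_landscape(li)
    gradient = st_inv.layers["env1"]

    suit_nat = suitability_surface(st_nat, sp)
    suit_inv = truncated_occupancy_surface(st_inv, sp)
    occ_nat = sample_occurrences(
        suit_nat, n_presences, seed=derive_seed(seed, "asym-occ-nat"),
        region_id="native",
    )
    occ_inv = sample_occurrences(
        suit_inv, n_presences, seed=derive_seed(seed, "asym-occ-inv"),
        region_id="invaded",
    )
    bg_nat = sample_background(
        full_box(st_nat), st_nat, n_background, derive_seed(seed, "asym-bg-nat")
    )
    bg_inv = sample_background(
        full_box(st_inv), st_inv, n_background, derive_seed(seed, "asym-bg-inv")
    )

    m_nat = fit_maxent(st_nat, bg_nat, occ_nat, beta=beta)
    m_inv = fit_maxent(st_inv, bg_inv, occ_inv, beta=beta)
    proj_nat = project(m_nat, st_inv)
    proj_inv = project(m_inv, st_inv)
    thr_nat = threshold_at_percentile(
        m_nat.suitability(st_nat.env_at_points(occ_nat.lon, occ_nat.lat)), percentile
    )
    thr_inv = threshold_at_percentile(
        m_inv.suitability(st_inv.env_at_points(occ_inv.lon, occ_inv.lat)), percentile
    )
    ranges = compare_binary_ranges(proj_inv, proj_nat, thr_inv, thr_nat)

    span = float(np.nanmax(gradient) - np.nanmin(gradient))
    bin_width = span / 30.0
    prof_nat = occupancy_profile(proj_nat, gradient, bin_width=bin_width,
                                 source="native-trained")
    prof_inv = occupancy_profile(proj_inv, gradient, bin_width=bin_width,
                                 source="invaded-trained")
    ks, ks_p = compare_profiles(prof_nat, prof_inv)

    pres_nat = (proj_nat.values >= thr_nat) & ~proj_nat.nodata_mask
    pres_inv = (proj_inv.values >= thr_inv) & ~proj_inv.nodata_mask
    n_inv_cells = int(pres_inv.sum())
    cell_inclusion = (
        float((pres_inv & pres_nat).sum() / n_inv_cells) if n_inv_cells else np.nan
    )
    return {
        "inclusion_cells_invaded_in_native": cell_inclusion,
        "inclusion_area_invaded_in_native": ranges.frac_1_in_2,
        "area_native_trained_km2": ranges.area_map2_km2,
        "area_invaded_trained_km2": ranges.area_map1_km2,
        "weighted_mean_native_trained": prof_nat.weighted_mean,
        "weighted_mean_invaded_trained": prof_inv.weighted_mean,
        "ks_stat": ks,
        "ks_p_advisory": ks_p,
        "threshold_native": thr_nat,
        "threshold_invaded": thr_inv,
    }
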