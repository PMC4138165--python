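"""Shared fixtures: toy grids and the standard synthetic study conditions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from nichedyn import make_landscape, schoener_d, similarity_test, sue_indices
from nichedyn.experiments import full_box, scenario_niche_grids
from nichedyn.niche import NicheGrid

SEEDS = (1, 2, 3)


def toy_grid(z, envelope=None, envelope_75=None) -> NicheGrid:
    """Wrap a raw occupancy array as a NicheGrid on a unit frame (tests only)."""
    z = np.asarray(z, dtype=float)
    env = np.ones_like(z, dtype=bool) if envelope is None else np.asarray(envelope, bool)
    env75 = env if envelope_75 is None else np.asarray(envelope_75, bool)
    return NicheGrid(
        R=z.shape[0],
        axis1_range=(0.0, 1.0),
        axis2_range=(0.0, 1.0),
        o=z.copy(),
        e=env.astype(float),
        z=z,
        envelope_100=env,
        envelope_75=env75,
    )


def scenario_grids(kind: str, seed: int, R: int = 100, shift_breadths: float = 2.0):
    """Niche grids for one scenario under the standard study conditions."""
    return scenario_niche_grids(kind, seed, R=R, shift_breadths=shift_breadths)


@pytest.fixture(scope="session")
def scenario_suite():
    """D and S/U/E across the three scenarios and seeds {1,2,3}, plus the
    conserved-scenario similarity p-values; computed once per session."""
    out: dict = {}
    for seed in SEEDS:
        gn, gi = scenario_grids("conserved", seed)
        s, u, e = sue_indices(gn, gi)
        out[("conserved", seed)] = {
            "D": schoener_d(gn, gi),
            "S": s, "U": u, "E": e,
            "p12": similarity_test(gn, gi, "1to2", n_reps=99, seed=seed),
            "p21": similarity_test(gn, gi, "2to1", n_reps=99, seed=seed + 1000),
        }
        gn, gi = scenario_grids("unfilled", seed)
        s, u, e = sue_indices(gn, gi)
        out[("unfilled", seed)] = {"D": schoener_d(gn, gi), "S": s, "U": u, "E": e}
        for shift in (1.0, 2.0, 3.0):
            gn, gi = scenario_grids("expanded", seed, shift_breadths=shift)
            s, u, e = sue_indices(gn, gi)
            out[("expanded", seed, shift)] = {
                "D": schoener_d(gn, gi), "S": s, "U": u, "E": e,
            }
    return out


@pytest.fixture(scope="session")
def small_stack():
    """A small deterministic landscape for cheap unit tests."""
    from nichedyn import VirtualLandscapeSpec

    spec = VirtualLandscapeSpec(
        region_id="unit", n_rows=30, n_cols=30, n_layers=3,
        spatial_smoothing=2.0, layer_correlation=0.2, seed=42,
    )
    return make_landscape(spec)
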