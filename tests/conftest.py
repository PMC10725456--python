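"""Shared fixtures: reduced-scale synthetic problems reused across tests.

Session scope keeps the expensive engine runs to one each; every fixture is
fully determined by its seed, so sharing does not couple tests.
"""

import dataclasses

import numpy as np
import pytest

import fncmeta as fm
from fncmeta.simulate import EffectRegion, SimulationConfig, region_field, simulate_expression, simulate_studies


SMALL_REGION = EffectRegion((10.0, -16.0, 12.0), 14.0, 0.8)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Reduced grid (24 x 28 x 24 at 6 mm) for fast engine runs."""
    return SimulationConfig(
        seed=11,
        grid_shape=(24, 28, 24),
        voxel_size_mm=6.0,
        regions=(SMALL_REGION,),
        n_samples=120,
        n_genes=200,
        n_drivers=20,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    table, truth = simulate_studies(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_meta(small_cfg, small_sim):
    table, truth = small_sim
    result = fm.sdm_z_map(table, truth["grid"], n_perm=50, seed=11)
    return result, truth


@pytest.fixture(scope="session")
def expression_problem(small_cfg):
    """Target map + expression matrix + z-scored X, y on the small grid."""
    grid = small_cfg.make_grid()
    target = 3.0 * region_field(grid, small_cfg.regions)
    em, drivers, tvals = simulate_expression(small_cfg, target, grid)
    sampled = fm.sample_map_values(target, grid, em.coords, radius_mm=6.0)
    retained = em.subset_samples(sampled.values.index)
    X = fm.zscore_columns(retained.values)
    y = fm.zscore_columns(sampled.values.to_numpy())
    return {
        "grid": grid,
        "target": target,
        "matrix": retained,
        "drivers": drivers,
        "X": X,
        "y": y,
        "coords": retained.sample_xyz,
    }
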