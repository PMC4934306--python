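"""Shared fixtures.

The expensive default-resolution field solves are session-scoped so the
acceptance checks and unit tests share them; everything else is built
per-test on deliberately small grids.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from probefield.geometry import SimulationDomain, default_probe_layout, voxelize
from probefield.solver import StimMode, StimulusConfig, solve_potential
from probefield.synthetic import disc_benchmark_grid, point_source_benchmark_grid

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_probe():
    return default_probe_layout()


@pytest.fixture(scope="session")
def default_grid(default_probe):
    return voxelize(default_probe, SimulationDomain())


@pytest.fixture(scope="session")
def field_single_100(default_grid):
    """Default-resolution single-side solve, s0, -100 uA (cathodic)."""
    stim = StimulusConfig(site_id="s0", current_uA=-100.0, mode=StimMode.SINGLE_SIDE)
    return solve_potential(default_grid, stim)


@pytest.fixture(scope="session")
def field_double_100(default_grid):
    """Default-resolution double-side solve, s0, -100 uA per site."""
    stim = StimulusConfig(site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE)
    return solve_potential(default_grid, stim)


@pytest.fixture(scope="session")
def small_grid(default_probe):
    """Coarse (15 um) reduced-domain probe grid for property tests."""
    ext = (1.0, 1.0, 1.4)
    dom = SimulationDomain(
        extents_mm=ext, voxel_size_um=15.0,
        probe_tip_mm=(ext[0] / 2, ext[1] / 2, ext[2] / 2 - 0.55),
    )
    with pytest.warns(UserWarning):  # sites clipped out of the reduced box
        return voxelize(default_probe, dom)


@pytest.fixture(scope="session")
def point_source_field():
    """Single-voxel source in uniform tissue with a spherical ground."""
    grid, ci = point_source_benchmark_grid(96, 20.0, 0.9)
    stim = StimulusConfig(site_id=None, current_uA=-100.0,
                          point_sources=((ci, -100.0),))
    fld = solve_potential(grid, stim)
    return fld, ci


@pytest.fixture(scope="session")
def disc_field_5um():
    """Disc electrode (a = 50 um) on an insulating plane, 5 um voxels."""
    grid = disc_benchmark_grid(50.0, 5.0, 0.25)
    stim = StimulusConfig(site_id="disc", current_uA=100.0, mode=StimMode.SINGLE_SIDE)
    return solve_potential(grid, stim), 0.25
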