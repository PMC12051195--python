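"""Shared fixtures: cheap converged slit states reused across test modules."""

from __future__ import annotations

import pytest
from hypothesis import settings

import padft

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_simple_182():
    """Monomeric 1:1 salt, 182 mM, mica-like wall charge."""
    arch = padft.build_linear_alternating(1, +1, b=4.0, d=4.0)
    return padft.SystemParams(cation_arch=arch, c_salt=0.182)


@pytest.fixture(scope="session")
def bulk_simple_182(params_simple_182):
    return padft.solve_bulk(params_simple_182)


@pytest.fixture(scope="session")
def state_simple_h30(params_simple_182, bulk_simple_182):
    """Converged r=1 slit at h = 30 Å; the workhorse state for diagnostics."""
    grid = padft.Grid(h=30.0, dz=0.25, d=4.0, b=4.0)
    return padft.solve_slit(params_simple_182, grid, bulk_simple_182)


@pytest.fixture(scope="session")
def pentamer_arch():
    return padft.build_linear_alternating(5, +1, b=4.0, d=4.0)


@pytest.fixture(scope="session")
def state_pentamer_h30():
    """Converged 5-mer polyampholyte slit at 182 mM, h = 30 Å."""
    arch = padft.build_linear_alternating(5, +1, b=4.0, d=4.0)
    params = padft.SystemParams(cation_arch=arch, c_salt=0.182)
    bulk = padft.solve_bulk(params)
    grid = padft.Grid(h=30.0, dz=0.25, d=4.0, b=4.0)
    return padft.solve_slit(params, grid, bulk)
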