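"""Shared fixtures: small phantoms built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from stereomorph.phantom import RegionSpec, make_phantom, populate_cells


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Unit-testing workhorse: a 1 mm-radius sphere, 50 µm voxels."""
    spec = RegionSpec("ball", 1, (2000.0, 2000.0, 2000.0),
                      (1000.0, 1000.0, 1000.0))
    vol, truth = make_phantom([spec], (80, 80, 100), (50.0, 50.0, 40.0))
    return vol, truth


@pytest.fixture(scope="session")
def cpu_phantom():
    """Caudate-putamen-like ellipsoid (10.9 mm³) with a neuron population."""
    spec = RegionSpec("CPu", 1, (3200.0, 3200.0, 3200.0),
                      (1100.0, 1100.0, 2200.0), target_volume_mm3=10.9)
    vol, truth = make_phantom([spec], (80, 80, 160), (80.0, 80.0, 40.0))
    cells = populate_cells(vol, "CPu", 66602, np.random.default_rng(7))
    return vol, truth, cells


@pytest.fixture(scope="session")
def shell_phantom():
    """Concentric spherical shell, R_in = 20, R_out = 28 unit voxels."""
    c = (32.0, 32.0, 32.0)
    inner = RegionSpec("inside", 1, c, (20.0, 20.0, 20.0))
    shell = RegionSpec("cortex", 2, c, (28.0, 28.0, 28.0),
                       inner_fraction=20.0 / 28.0)
    vol, truth = make_phantom([inner, shell], (64, 64, 64), (1.0, 1.0, 1.0))
    return vol, truth
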