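"""Shared fixtures: one slab geometry, a session-scoped Monte Carlo
reference run and library, and a synthetic IRF.

Session scope keeps the Monte Carlo cost paid once; all fixture seeds are
fixed so the suite is deterministic.
"""

import numpy as np
import pytest

import tddos as td


@pytest.fixture(scope="session")
def geometry():
    return td.SlabGeometry(thickness=1.0, n_sample=1.41, n_external=1.5, detector_radius=0.5)


@pytest.fixture(scope="session")
def grid():
    # 2048 x 5 ps: same span as the 4096 x 2.5 ps default at half the cost
    return td.TimeGrid(0.0, 5.0, 2048)


@pytest.fixture(scope="session")
def mc10(geometry, grid):
    """Reference Monte Carlo run at mus' = 10 /cm, 1e6 photons."""
    return td.simulate_reference_tpsf(geometry, 10.0, grid, 10**6, seed=1)


@pytest.fixture(scope="session")
def library(geometry, grid):
    """10-node geometric library over 3-28 /cm, 2e5 photons per node:
    covers the synthetic treatment trajectories."""
    nodes = np.geomspace(3.0, 28.0, 10)
    return td.build_library(geometry, nodes, grid, 2 * 10**5, seed=42)


@pytest.fixture(scope="session")
def irf80(grid):
    """80 ps FWHM Gaussian IRF peaked at 300 ps."""
    return td.synthesize_irf(80.0, "gaussian", grid, 300.0)


def rebin(values, factor):
    """Aggregate adjacent bins (noise suppression for shape comparisons)."""
    values = np.asarray(values, dtype=float)
    n = len(values) // factor
    return values[: n * factor].reshape(n, factor).sum(axis=1)


def window_shape_deviation(test_values, oracle_values, factor=8, config=None):
    """Max relative deviation of area-normalized curves over the fit window
    of the oracle, after rebinning by ``factor``."""
    from tddos.inversion import fit_window

    a = rebin(test_values, factor)
    b = rebin(oracle_values, factor)
    w0, w1 = fit_window(b, config)
    a = a[w0 : w1 + 1]
    b = b[w0 : w1 + 1]
    a = a / a.sum()
    b = b / b.sum()
    return np.abs(a - b) / b
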