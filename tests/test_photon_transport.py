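"""Monte Carlo forward model: causality, energy bookkeeping, Beer-Lambert
factorization, RTE scaling, library interpolation, and the diffusion
oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tddos as td
from tddos._kernels import _fresnel_reflectance
from tddos.core import C_CM_PER_PS

from conftest import window_shape_deviation


def make_tpsf(grid, values, mus_prime=10.0, n_sample=1.41):
    return td.TPSF(
        grid=grid,
        values=np.asarray(values, dtype=float),
        mus_prime=mus_prime,
        n_sample=n_sample,
        photons_launched=10**6,
    )


class TestSimulation:
    def test_causality_no_weight_before_ballistic_time(self, geometry, grid, mc10):
        """No transmitted photon can arrive before thickness * n / c."""
        ballistic = geometry.ballistic_time
        assert ballistic == pytest.approx(1.0 * 1.41 / 0.0299792458)
        early = grid.bin_edges[1:] <= ballistic
        assert mc10.values[early].sum() == 0.0

    def test_energy_bookkeeping_closes(self, mc10):
        """Transmitted + reflected + truncated equals launched exactly."""
        t = mc10.tallies
        assert t["transmitted"] + t["reflected"] + t["truncated"] == mc10.photons_launched
        assert mc10.total_weight <= 1.0

    def test_more_scattering_lengthens_transit(self, geometry, grid):
        lo = td.simulate_reference_tpsf(geometry, 5.0, grid, 2 * 10**5, seed=7)
        hi = td.simulate_reference_tpsf(geometry, 10.0, grid, 2 * 10**5, seed=7)
        assert hi.mean_time > lo.mean_time

    def test_same_seed_is_bit_identical(self, geometry, grid):
        a = td.simulate_reference_tpsf(geometry, 8.0, grid, 5 * 10**4, seed=3)
        b = td.simulate_reference_tpsf(geometry, 8.0, grid, 5 * 10**4, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_curve_flagged_not_silent(self, grid):
        thick = td.SlabGeometry(thickness=5.0, detector_radius=0.05)
        with pytest.warns(UserWarning, match="empty"):
            tp = td.simulate_reference_tpsf(thick, 60.0, grid, 10**4, seed=5)
        assert tp.is_empty

    def test_preconditions(self, geometry, grid):
        with pytest.raises(ValueError):
            td.simulate_reference_tpsf(geometry, -1.0, grid, 10**5, seed=0)
        with pytest.raises(ValueError):
            td.simulate_reference_tpsf(geometry, 10.0, grid, 100, seed=0)


class TestFresnel:
    def test_normal_incidence_matches_closed_form(self):
        r = _fresnel_reflectance(1.0, 1.41, 1.5)
        assert r == pytest.approx(((1.41 - 1.5) / (1.41 + 1.5)) ** 2)

    def test_total_internal_reflection(self):
        # from dense to rare medium beyond the critical angle
        cos_crit = math.sqrt(1.0 - (1.0 / 1.5) ** 2)
        assert _fresnel_reflectance(0.5 * cos_crit, 1.5, 1.0) == 1.0

    def test_grazing_incidence_reflects_fully(self):
        assert _fresnel_reflectance(1e-9, 1.41, 1.5) == pytest.approx(1.0, abs=1e-3)


class TestApplyAbsorption:
    def test_printed_formula_value(self, grid):
        """One bin at t = 1000 ps, n = 1.41, mua = 0.1 /cm ->
        factor exp(-0.1 * (0.029979/1.41) * 1000) ~ 0.1193."""
        values = np.zeros(grid.n_bins)
        idx = int((1000.0 - grid.t0) / grid.dt)
        values[idx] = 1.0
        tp = make_tpsf(grid, values)
        out = td.apply_absorption(tp, 0.1)
        t_center = grid.centers[idx]
        expected = math.exp(-0.1 * (C_CM_PER_PS / 1.41) * t_center)
        assert out.values[idx] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1193, rel=2e-2)

    def test_zero_absorption_is_identity(self, mc10):
        out = td.apply_absorption(mc10, 0.0)
        np.testing.assert_array_equal(out.values, mc10.values)

    def test_input_unchanged(self, mc10):
        before = mc10.values.copy()
        td.apply_absorption(mc10, 0.3)
        np.testing.assert_array_equal(mc10.values, before)

    def test_negative_absorption_rejected(self, mc10):
        with pytest.raises(ValueError):
            td.apply_absorption(mc10, -0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mua1=st.floats(0.0, 1.0),
        mua2=st.floats(0.0, 1.0),
    )
    def test_composition_is_additive(self, mua1, mua2):
        grid = td.TimeGrid(0.0, 5.0, 256)
        rng = np.random.default_rng(0)
        tp = make_tpsf(grid, rng.random(256) * 1e-3)
        seq = td.apply_absorption(td.apply_absorption(tp, mua1), mua2)
        direct = td.apply_absorption(tp, mua1 + mua2)
        np.testing.assert_allclose(seq.values, direct.values, rtol=1e-12, atol=0)
        assert seq.mua == pytest.approx(direct.mua)


class TestScaling:
    def test_identity_at_k1(self, mc10):
        out = td.scale_tpsf(mc10, 1.0)
        np.testing.assert_array_equal(out.values, mc10.values)
        assert out.grid == mc10.grid

    def test_transmitted_fraction_conserved(self, mc10):
        out = td.scale_tpsf(mc10, 2.0)
        assert out.total_weight == mc10.total_weight
        assert out.mus_prime == mc10.mus_prime / 2.0
        assert out.grid.dt == 2.0 * mc10.grid.dt

    def test_rejects_absorbed_curves(self, mc10):
        absorbed = td.apply_absorption(mc10, 0.1)
        with pytest.raises(ValueError):
            td.scale_tpsf(absorbed, 2.0)


class TestLibrary:
    def test_node_query_returns_node_curve(self, library):
        node = float(library.grid_mus_prime[3])
        out = td.interpolate_library(library, node)
        np.testing.assert_array_equal(out.values, library.curves[3].values)

    def test_out_of_range_raises(self, library):
        with pytest.raises(ValueError, match="outside library range"):
            td.interpolate_library(library, 100.0)
        with pytest.raises(ValueError, match="outside library range"):
            td.interpolate_library(library, 0.5)

    def test_mean_time_monotone_between_nodes(self, library):
        queries = np.linspace(8.0, 12.0, 9)
        times = [td.interpolate_library(library, q).mean_time for q in queries]
        assert np.all(np.diff(times) > 0)

    def test_rebuild_same_seed_bit_identical(self, geometry, grid, library):
        rebuilt = td.build_library(
            geometry, library.grid_mus_prime, grid, library.n_photons, library.seed
        )
        for a, b in zip(rebuilt.curves, library.curves):
            np.testing.assert_array_equal(a.values, b.values)

    def test_single_node_library(self, geometry, grid):
        lib = td.build_library(geometry, np.array([10.0]), grid, 10**4, seed=9)
        out = td.interpolate_library(lib, 10.0)
        np.testing.assert_array_equal(out.values, lib.curves[0].values)

    def test_sparse_grid_warns(self, geometry, grid):
        with pytest.warns(UserWarning, match="sparse"):
            td.build_library(geometry, np.array([5.0, 20.0]), grid, 10**4, seed=9)

    def test_interpolation_matches_direct_mc_at_midpoint(self, geometry, grid):
        """Shape interpolated from nodes {8, 12} agrees with a direct
        simulation at 10 /cm within 3% over the fit window (80 ps bins to
        suppress counting noise)."""
        lib = td.build_library(geometry, np.array([8.0, 12.0]), grid, 4 * 10**6, seed=3)
        mid = td.interpolate_library(lib, 10.0)
        direct = td.simulate_reference_tpsf(geometry, 10.0, grid, 4 * 10**6, seed=77)
        dev = window_shape_deviation(mid.values, direct.values, factor=16)
        assert dev.max() < 0.03
        assert abs(mid.mean_time / direct.mean_time - 1.0) < 0.01


class TestDiffusionOracle:
    def test_flux_vanishes_at_early_and_late_times(self, geometry):
        long_grid = td.TimeGrid(0.0, 20.0, 4096)  # out to 82 ns
        da = td.da_transmittance(geometry, 0.0, 10.0, long_grid)
        assert da.values[0] < 1e-9 * da.values.max()
        assert da.values[-1] < 1e-12 * da.values.max()

    def test_beer_lambert_factorizes(self, geometry, grid):
        direct = td.da_transmittance(geometry, 0.07, 10.0, grid)
        factored = td.apply_absorption(td.da_transmittance(geometry, 0.0, 10.0, grid), 0.07)
        np.testing.assert_allclose(direct.values, factored.values, rtol=1e-12, atol=0)

    def test_warns_outside_diffusive_regime(self, geometry, grid):
        with pytest.warns(UserWarning, match="diffusive"):
            td.da_transmittance(geometry, 5.0, 10.0, grid)

    def test_mean_time_matches_monte_carlo(self, geometry, mc10):
        da = td.da_transmittance(geometry, 0.0, 10.0, mc10.grid)
        assert da.mean_time == pytest.approx(mc10.mean_time, rel=0.02)
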