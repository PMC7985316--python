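"""Synthetic tissue generator: chromophore basis invariants, trajectory
phenomenology at the two treatment set points, dataset synthesis."""

import numpy as np
import pytest

import tddos as td
from tddos.synthetic import (
    BROADBAND_WAVELENGTHS,
    TrajectoryParams,
    TreatmentProtocol,
    compose_absorption,
    default_basis,
    evolve_state,
    generate_dataset,
    temperature_profile,
)

WL = BROADBAND_WAVELENGTHS


@pytest.fixture(scope="module")
def params():
    return TrajectoryParams()


@pytest.fixture(scope="module")
def basis():
    return default_basis(WL)


class TestBasis:
    def test_invariants(self, basis):
        basis.validate()  # raises on violation

    def test_hb_peak_position(self, basis):
        assert 750 <= WL[np.argmax(basis.hb())] <= 770

    def test_water_peak_position(self, basis):
        assert 965 <= WL[np.argmax(basis.water())] <= 985

    def test_methb_dominates_heme_780_900(self, basis):
        band = (WL >= 780) & (WL <= 900)
        assert np.all(basis.methb()[band] > basis.hb()[band])
        assert np.all(basis.methb()[band] > basis.hbo2()[band])

    def test_grid_outside_band_rejected(self):
        with pytest.raises(ValueError):
            default_basis(np.arange(600.0, 1101.0, 10.0))

    def test_water_shift_and_narrowing(self):
        """delta = -5 nm, width factor 0.8: the spline-located peak moves
        by -5 +- 0.2 nm and the FWHM scales by 0.8 +- 5% (dense grid)."""
        dense = np.arange(650.0, 1100.0, 0.1)
        b = default_basis(dense)

        def peak_and_fwhm(curve):
            idx = int(np.argmax(curve))
            half = curve[idx] / 2.0
            above = np.nonzero(curve >= half)[0]
            return dense[idx], dense[above[-1]] - dense[above[0]]

        p0, f0 = peak_and_fwhm(b.water(0.0, 1.0))
        p1, f1 = peak_and_fwhm(b.water(-5.0, 0.8))
        assert p1 - p0 == pytest.approx(-5.0, abs=0.2)
        assert f1 / f0 == pytest.approx(0.8, rel=0.05)


class TestComposeAbsorption:
    def test_all_zero_state_gives_zero(self, basis):
        state = td.TissueState(0, 0, 0, 0, 0, 1.0, 0, a=1.0, b=1.0, charring_amp=0.0, temperature=23.0)
        np.testing.assert_array_equal(compose_absorption(state, basis), np.zeros(len(WL)))

    def test_linear_in_concentrations(self, basis, params):
        proto = TreatmentProtocol(target_temperature=70.0)
        s1 = evolve_state(params, proto, 0.0)
        s2 = td.TissueState(
            2 * s1.c_hb, 2 * s1.c_hbo2, 2 * s1.c_methb, min(2 * s1.water_fraction, 1.0),
            s1.water_shift, s1.water_width, s1.hb_shift, s1.a, s1.b,
            2 * s1.charring_amp, s1.temperature,
        )
        # doubling concentrations (water fraction capped aside) doubles mua
        a1 = compose_absorption(s1, basis)
        a2 = compose_absorption(s2, basis)
        scale = min(2.0, s2.water_fraction / s1.water_fraction)
        if scale == 2.0:
            np.testing.assert_allclose(a2, 2 * a1, rtol=1e-12)

    def test_non_negative(self, basis, params):
        proto = TreatmentProtocol(target_temperature=105.0)
        for t in (0.0, 300.0, 780.0):
            assert np.all(compose_absorption(evolve_state(params, proto, t), basis) >= 0)


class TestTemperatureProfile:
    def test_starts_at_room_temperature(self):
        proto = TreatmentProtocol(target_temperature=105.0)
        assert temperature_profile(proto, 0.0) == 23.0

    def test_reaches_target_at_ramp_end(self):
        proto = TreatmentProtocol(target_temperature=105.0)
        assert temperature_profile(proto, proto.ramp_duration) == pytest.approx(105.0)

    def test_monotone_through_ramp_and_hold(self):
        proto = TreatmentProtocol(target_temperature=70.0)
        t = np.linspace(0.0, proto.treatment_span, 200)
        temps = temperature_profile(proto, t)
        assert np.all(np.diff(temps) >= -1e-12)

    def test_cooling_returns_toward_room(self):
        proto = TreatmentProtocol(target_temperature=105.0, cooling=True, cooling_duration=1500.0)
        end = temperature_profile(proto, proto.treatment_span + 1500.0)
        assert 23.0 < end < 40.0


class TestEvolveState:
    def test_native_state_at_t0(self, params):
        proto = TreatmentProtocol(target_temperature=105.0)
        s = evolve_state(params, proto, 0.0)
        assert s.c_methb == 0.0
        assert s.charring_amp == 0.0
        assert s.water_shift == pytest.approx(0.0, abs=0.2)
        assert s.water_width == pytest.approx(1.0, abs=0.05)
        assert s.hb_shift == 0.0
        assert s.a == pytest.approx(params.a0, rel=0.01)

    def test_70C_never_converts_or_chars(self, params):
        """The 70 C protocol never crosses the 75 C metHb threshold or the
        100 C charring onset."""
        proto = TreatmentProtocol(target_temperature=70.0)
        for t in np.linspace(0.0, proto.treatment_span, 14):
            s = evolve_state(params, proto, float(t))
            assert s.c_methb == 0.0
            assert s.charring_amp == 0.0

    def test_105C_end_of_hold(self, params):
        """Overtreatment end state: scattering gain in [2.5, 3.5] with
        metHb and charring both present."""
        proto = TreatmentProtocol(target_temperature=105.0)
        s0 = evolve_state(params, proto, 0.0)
        s = evolve_state(params, proto, proto.treatment_span)
        assert 2.5 <= s.a / s0.a <= 3.5
        assert s.c_methb > 0.0
        assert s.charring_amp > 0.0

    def test_70C_plateau_in_band(self, params):
        proto = TreatmentProtocol(target_temperature=70.0)
        s0 = evolve_state(params, proto, 0.0)
        gains = [
            evolve_state(params, proto, float(t)).a / s0.a
            for t in np.linspace(0.0, proto.treatment_span, 14)
        ]
        assert 1.7 <= max(gains) <= 2.3

    def test_trajectory_continuous(self, params):
        proto = TreatmentProtocol(target_temperature=105.0)
        ts = np.linspace(0.0, proto.treatment_span, 400)
        a = np.array([evolve_state(params, proto, float(t)).a for t in ts])
        water = np.array([evolve_state(params, proto, float(t)).water_fraction for t in ts])
        assert np.max(np.abs(np.diff(a))) < 0.12 * params.a0
        assert np.max(np.abs(np.diff(water))) < 0.02

    def test_cooling_partially_reverses_water_band(self, params):
        proto = TreatmentProtocol(
            target_temperature=105.0, cooling=True, cooling_duration=1500.0
        )
        end = evolve_state(params, proto, proto.treatment_span)
        cooled = evolve_state(params, proto, proto.total_span)
        # shift relaxes toward zero, width back toward 1 -- but only partly
        assert abs(cooled.water_shift) < abs(end.water_shift)
        assert cooled.water_shift != 0.0
        assert end.water_width < cooled.water_width < 1.0
        # conversion and charring are irreversible
        assert cooled.c_methb >= end.c_methb
        assert cooled.charring_amp >= end.charring_amp

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            TrajectoryParams(scattering_onset=80.0)

    def test_outside_span_rejected(self, params):
        proto = TreatmentProtocol(target_temperature=70.0)
        with pytest.raises(ValueError):
            evolve_state(params, proto, proto.total_span + 100.0)


@pytest.fixture(scope="module")
def small_kwargs(library, irf80, geometry, params):
    return dict(
        params=params,
        protocol=TreatmentProtocol(target_temperature=105.0),
        geometry=geometry,
        library=library,
        irf=irf80,
        counts_per_curve=10**5,
    )


class TestGenerateDataset:

    def test_broadband_record_count(self, small_kwargs):
        ds = generate_dataset(**small_kwargs, seed=1, timestamps=np.array([0.0, 780.0]))
        assert len(ds.records) == 2 * 46

    def test_five_wavelength_protocol_counts(self, small_kwargs):
        kw = dict(small_kwargs)
        kw["protocol"] = TreatmentProtocol(
            target_temperature=105.0, sampling_mode="five-wavelength"
        )
        ds = generate_dataset(**kw, seed=1, timestamps=np.arange(0.0, 601.0, 100.0))
        assert len(ds.records) == 7 * 5
        assert set(r.wavelength for r in ds.records) == {770.0, 840.0, 910.0, 980.0, 1060.0}

    def test_protocol_timestamp_arithmetic(self):
        assert len(TreatmentProtocol(sampling_mode="broadband").timestamps()) == 13
        assert len(TreatmentProtocol(sampling_mode="five-wavelength").timestamps()) == 61

    def test_same_seed_bit_identical(self, small_kwargs):
        ts = np.array([0.0, 780.0])
        wl = np.array([770.0, 980.0])
        a = generate_dataset(**small_kwargs, seed=5, timestamps=ts, wavelengths=wl)
        b = generate_dataset(**small_kwargs, seed=5, timestamps=ts, wavelengths=wl)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.counts, rb.counts)

    def test_replicates_stay_within_variability(self, small_kwargs):
        ts = np.array([0.0])
        ds = generate_dataset(
            **small_kwargs, seed=2, n_samples=3, timestamps=ts,
            wavelengths=np.array([770.0, 980.0]),
        )
        truths = [ds.truth[(i, 0.0)] for i in range(3)]
        mean = np.mean([t.mua for t in truths], axis=0)
        for t in truths:
            assert np.all(np.abs(t.mua - mean) / mean < 0.15)

    def test_truth_paired_with_records(self, small_kwargs):
        ts = np.array([0.0, 780.0])
        ds = generate_dataset(**small_kwargs, seed=3, timestamps=ts)
        assert set(ds.truth) == {(0, 0.0), (0, 780.0)}
        assert len(ds.truth[(0, 0.0)]) == 46
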