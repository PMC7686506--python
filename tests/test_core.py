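"""Homodyne forward model, demodulation, calibration and phasor algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdflim.core import (
    CalibrationError,
    DecayModel,
    ModulationConfig,
    RawFrameStack,
    apparent_phase_lifetime,
    calibrate,
    demodulate,
    lifetime_to_phasor,
    mixture_phasor,
    modulation_lifetime,
    phase_lifetime,
    reconstruct_map,
    simulate_frames,
    solve_long_fraction,
)

F10 = 10e6
OMEGA10 = 2 * np.pi * F10


def make_stack(phase, modulation, dc, k=16, f=F10):
    cfg = ModulationConfig(frequency_hz=f, n_phase_steps=k)
    theta = cfg.phase_offsets_rad
    frames = dc * (1 + modulation * np.cos(theta - phase))
    return RawFrameStack(frames[:, None, None] * np.ones((1, 2, 2)), cfg)


class TestDemodulate:
    @pytest.mark.parametrize("k", [3, 4, 8, 16])
    @pytest.mark.parametrize("phase,mod,dc", [(np.pi / 3, 0.5, 100.0), (1.2, 0.9, 7.0)])
    def test_exact_on_noiseless_sinusoid(self, k, phase, mod, dc):
        """The DFT estimator is exact for any K >= 3 equally spaced steps."""
        res = demodulate(make_stack(phase, mod, dc, k=k))
        assert np.allclose(res.phase_rad, phase, atol=1e-12)
        assert np.allclose(res.modulation, mod, atol=1e-12)
        assert np.allclose(res.dc, dc, atol=1e-10)

    def test_constant_frames_have_zero_ac(self):
        res = demodulate(make_stack(0.0, 0.0, 50.0))
        assert np.allclose(res.modulation, 0.0, atol=1e-12)
        assert np.allclose(res.dc, 50.0)

    def test_dark_pixels_flagged_not_raised(self):
        cfg = ModulationConfig()
        frames = np.zeros((16, 2, 2))
        frames[:, 0, 0] = 10.0
        res = demodulate(RawFrameStack(frames, cfg))
        assert res.valid[0, 0] and not res.valid[1, 1]
        assert np.isnan(res.phase_rad[1, 1])

    def test_poisson_phase_error_small_at_high_counts(self, rng):
        """Monte-Carlo: phase recovered within +-0.01 rad at dc = 1e4."""
        cfg = ModulationConfig()
        theta = cfg.phase_offsets_rad
        true_phase, true_mod, dc = 1.0, 0.4, 1e4
        expect = dc * (1 + true_mod * np.cos(theta - true_phase))
        frames = rng.poisson(expect[:, None], size=(16, 1000)).astype(float)
        res = demodulate(RawFrameStack(frames[:, :, None], cfg))
        assert abs(np.mean(res.phase_rad) - true_phase) < 0.01


class TestSimulateFrames:
    def test_resonant_mono_exponential(self):
        """At omega*tau = 1 the phase is 45 degrees and modulation 1/sqrt(2)."""
        tau = 1e9 / OMEGA10
        cfg = ModulationConfig()
        stack = simulate_frames(DecayModel.mono(tau), 100.0, cfg)
        expected = 100.0 * (1 + np.cos(cfg.phase_offsets_rad - np.pi / 4) / np.sqrt(2))
        assert np.allclose(stack.frames[:, 0, 0], expected)

    def test_zero_lifetime_scatterer(self):
        cfg = ModulationConfig()
        stack = simulate_frames(DecayModel.mono(0.0 + 1e-300), 50.0, cfg)
        # zero-lifetime limit: full modulation, zero phase
        assert np.allclose(stack.frames[:, 0, 0], 50.0 * (1 + np.cos(cfg.phase_offsets_rad)))

    def test_rejects_nonphysical_instrument(self):
        with pytest.raises(ValueError):
            simulate_frames(
                DecayModel.mono(1.0), 10.0, ModulationConfig(), instrument_modulation=0.0
            )

    def test_poisson_noise_seeded(self):
        a = simulate_frames(DecayModel.mono(2.0), 100.0, ModulationConfig(),
                            noise="poisson", seed=7, shape=(4, 4))
        b = simulate_frames(DecayModel.mono(2.0), 100.0, ModulationConfig(),
                            noise="poisson", seed=7, shape=(4, 4))
        assert np.array_equal(a.frames, b.frames)


class TestCalibrate:
    def test_ideal_scatterer_gives_identity(self):
        stack = simulate_frames(DecayModel.mono(1e-300), 100.0, ModulationConfig())
        cal = calibrate(stack, 0.0)
        assert abs(cal.instrument_phase_rad) < 1e-12
        assert abs(cal.instrument_modulation - 1.0) < 1e-12

    def test_recovers_instrument_from_lifetime_reference(self):
        """Closed-form inversion of the forward model on noiseless frames."""
        cfg = ModulationConfig()
        stack = simulate_frames(
            DecayModel.mono(4.0), 200.0, cfg,
            instrument_phase_rad=0.3, instrument_modulation=0.8,
        )
        cal = calibrate(stack, 4.0)
        assert abs(cal.instrument_phase_rad - 0.3) < 1e-10
        assert abs(cal.instrument_modulation - 0.8) < 1e-10

    def test_resonant_reference_true_phase_is_45_degrees(self):
        tau_ref = 1e9 / OMEGA10  # omega * tau_ref = 1
        stack = simulate_frames(DecayModel.mono(tau_ref), 100.0, ModulationConfig())
        demod = demodulate(stack)
        assert np.allclose(demod.phase_rad, np.pi / 4, atol=1e-12)
        cal = calibrate(stack, tau_ref)
        assert abs(cal.instrument_phase_rad) < 1e-10

    def test_zero_modulation_reference_fails(self):
        cfg = ModulationConfig()
        stack = RawFrameStack(np.full((16, 2, 2), 30.0), cfg)
        with pytest.raises(CalibrationError):
            calibrate(stack, 0.0)


class TestLifetimeConversions:
    def test_phase_lifetime_values(self):
        assert phase_lifetime(0.0, F10) == 0.0
        assert phase_lifetime(np.pi / 4, F10) == pytest.approx(15.9155, abs=1e-3)
        assert phase_lifetime(np.radians(30), F10) == pytest.approx(9.189, abs=1e-2)

    def test_phase_lifetime_invalid_beyond_quarter_turn(self):
        assert np.isnan(phase_lifetime(np.pi / 2, F10))
        assert np.isnan(phase_lifetime(-0.1, F10))

    def test_modulation_lifetime_values(self):
        assert modulation_lifetime(1.0, F10) == pytest.approx(0.0, abs=1e-9)
        assert modulation_lifetime(1 / np.sqrt(2), F10) == pytest.approx(15.9155, abs=1e-3)
        assert modulation_lifetime(0.9, F10) == pytest.approx(7.708, abs=1e-2)
        assert np.isnan(modulation_lifetime(1.2, F10))


class TestPhasorAlgebra:
    @given(st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_mono_exponential_on_universal_semicircle(self, tau):
        p = lifetime_to_phasor(tau, F10)
        assert abs((p.g - 0.5) ** 2 + p.s**2 - 0.25) < 1e-12

    def test_phasor_landmarks(self):
        p0 = lifetime_to_phasor(0.0, F10)
        assert (p0.g, p0.s) == (1.0, 0.0)
        apex = lifetime_to_phasor(1e9 / OMEGA10, F10)
        assert apex.g == pytest.approx(0.5) and apex.s == pytest.approx(0.5)
        p16 = lifetime_to_phasor(16.0, F10)
        assert p16.g == pytest.approx(0.497, abs=1e-3)
        assert p16.s == pytest.approx(0.500, abs=1e-3)

    def test_mixture_collinearity(self):
        """Phasors of all mixtures lie on the chord between the components."""
        p1 = lifetime_to_phasor(16.0, F10)
        p2 = lifetime_to_phasor(1.9, F10)
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            pm = mixture_phasor(DecayModel.biexponential(16.0, 1.9, alpha), F10)
            cross = (pm.g - p2.g) * (p1.s - p2.s) - (pm.s - p2.s) * (p1.g - p2.g)
            assert abs(cross) < 1e-12

    def test_midpoint_mixture(self):
        p1 = lifetime_to_phasor(16.0, F10)
        p2 = lifetime_to_phasor(1.9, F10)
        pm = mixture_phasor(DecayModel.biexponential(16.0, 1.9, 0.5), F10)
        assert pm.g == pytest.approx((p1.g + p2.g) / 2, abs=1e-15)
        assert pm.s == pytest.approx((p1.s + p2.s) / 2, abs=1e-15)

    def test_apparent_lifetime_identity_for_mono(self):
        for tau in (1.9, 16.0):
            assert apparent_phase_lifetime(DecayModel.mono(tau), F10) == pytest.approx(tau)

    def test_apparent_lifetime_of_ppix_like_mixture(self):
        tau = apparent_phase_lifetime(DecayModel.biexponential(16.0, 1.9, 0.783), F10)
        assert tau == pytest.approx(11.0, abs=0.01)

    def test_apparent_lifetime_monotone_in_long_fraction(self):
        taus = [
            apparent_phase_lifetime(DecayModel.biexponential(16.0, 1.9, a), F10)
            for a in np.linspace(0.01, 1.0, 25)
        ]
        assert np.all(np.diff(taus) > 0)


class TestSolveLongFraction:
    def test_boundaries(self):
        assert solve_long_fraction(16.0, 16.0, 1.9, F10) == pytest.approx(1.0, abs=1e-12)
        assert solve_long_fraction(1.9 + 1e-9, 16.0, 1.9, F10) == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search(self):
        """Independent oracle: dense scan over alpha minimizing |tau_app - 11|."""
        alphas = np.linspace(0.0, 1.0, 200001)
        p1 = lifetime_to_phasor(16.0, F10)
        p2 = lifetime_to_phasor(1.9, F10)
        g = alphas * p1.g + (1 - alphas) * p2.g
        s = alphas * p1.s + (1 - alphas) * p2.s
        tau_app = s / g / OMEGA10 * 1e9
        best = alphas[np.argmin(np.abs(tau_app - 11.0))]
        assert solve_long_fraction(11.0, 16.0, 1.9, F10) == pytest.approx(best, abs=1e-5)
        assert best == pytest.approx(0.783, abs=1e-3)

    @given(st.floats(min_value=1.91, max_value=16.0))
    @settings(max_examples=100, deadline=None)
    def test_inverts_apparent_lifetime(self, target):
        alpha = solve_long_fraction(target, 16.0, 1.9, F10)
        decay = DecayModel.biexponential(16.0, 1.9, min(max(alpha, 0.0), 1.0))
        assert apparent_phase_lifetime(decay, F10) == pytest.approx(target, rel=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            solve_long_fraction(1.5, 16.0, 1.9, F10)
        with pytest.raises(ValueError):
            solve_long_fraction(17.0, 16.0, 1.9, F10)


class TestReconstructMap:
    def test_noiseless_round_trip_at_5ns(self):
        cfg = ModulationConfig()
        ref = simulate_frames(DecayModel.mono(1e-300), 100.0, cfg)
        cal = calibrate(ref, 0.0)
        stack = simulate_frames(DecayModel.mono(5.0), 100.0, cfg, shape=(8, 8))
        lt = reconstruct_map(stack, cal)
        assert lt.valid.all()
        assert np.allclose(lt.tau_ns, 5.0, atol=1e-9)

    def test_mixture_maps_to_apparent_lifetime(self):
        cfg = ModulationConfig()
        cal = calibrate(simulate_frames(DecayModel.mono(1e-300), 100.0, cfg), 0.0)
        decay = DecayModel.biexponential(16.0, 1.9, 0.783)
        lt = reconstruct_map(simulate_frames(decay, 100.0, cfg, shape=(4, 4)), cal)
        assert np.allclose(lt.tau_ns, 11.0, atol=0.01)

    @given(
        tau=st.floats(min_value=0.1, max_value=16.0),
        phi_inst=st.floats(min_value=-0.5, max_value=0.5),
        m_inst=st.floats(min_value=0.5, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_property_any_instrument(self, tau, phi_inst, m_inst):
        """simulate -> calibrate -> reconstruct recovers tau to 1e-9 relative.

        Instrument gain stays at or below 1: a gain above unity on a fully
        modulated scatterer would drive frame intensities negative, which no
        physical detector produces.
        """
        cfg = ModulationConfig()
        ref = simulate_frames(
            DecayModel.mono(1e-300), 100.0, cfg,
            instrument_phase_rad=phi_inst, instrument_modulation=m_inst,
        )
        cal = calibrate(ref, 0.0)
        stack = simulate_frames(
            DecayModel.mono(tau), 100.0, cfg, shape=(2, 2),
            instrument_phase_rad=phi_inst, instrument_modulation=m_inst,
        )
        lt = reconstruct_map(stack, cal)
        assert lt.valid.all()
        assert np.allclose(lt.tau_ns, tau, rtol=1e-9, atol=1e-9)

    def test_poisson_median_within_one_percent(self, rng):
        cfg = ModulationConfig()
        cal = calibrate(simulate_frames(DecayModel.mono(1e-300), 1e4, cfg), 0.0)
        tau = 15.9
        stack = simulate_frames(
            DecayModel.mono(tau), 1e4, cfg, shape=(128, 128), noise="poisson", seed=rng
        )
        lt = reconstruct_map(stack, cal)
        assert abs(np.nanmedian(lt.tau_ns) - tau) / tau < 0.01

    def test_config_mismatch_raises(self):
        cfg = ModulationConfig()
        other = ModulationConfig(frequency_hz=40e6)
        cal = calibrate(simulate_frames(DecayModel.mono(1e-300), 100.0, cfg), 0.0)
        stack = simulate_frames(DecayModel.mono(2.0), 100.0, other)
        with pytest.raises(ValueError):
            reconstruct_map(stack, cal)
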