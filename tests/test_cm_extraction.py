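"""Stimulus composition, FFT extraction vs. the quadrature oracle,
phase unwrapping and smoothing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ecochg_monitor as em
from conftest import make_tracing


def _epoch_of(wave, rate=22050.0, t0=0.0):
    return em.EpochRecord(wave, rate, t0)


class TestComposeAndExtract:
    def test_single_tone_spectrum_and_phase_convention(self):
        stim = em.StimulusSet((em.ToneSpec(507.0),))
        wave = 10.0 * em.compose_stimulus(stim)
        spec = np.abs(np.fft.rfft(wave))
        assert np.argmax(spec) == 507
        mask = np.ones(len(spec), bool)
        mask[507] = False
        assert spec[mask].max() < 1e-6 * spec[507]
        (est,) = em.extract_cm(_epoch_of(wave), stim)
        assert est.amplitude == pytest.approx(10.0, rel=1e-9)
        # a pure sine reports -π/2 under the DFT-coefficient convention
        assert est.phase == pytest.approx(-math.pi / 2, abs=1e-9)

    def test_four_tone_bins_hold_amplitude_times_half_n(self):
        stim = em.default_stimulus()
        amps = [3.0, 5.0, 7.0, 11.0]
        wave = em.compose_stimulus(stim, amplitudes=amps)
        n = len(wave)
        spec = np.abs(np.fft.rfft(wave))
        for f, a in zip(stim.frequencies, amps):
            assert spec[int(f)] == pytest.approx(a * n / 2, rel=1e-9)
        mask = np.ones(len(spec), bool)
        mask[[int(f) for f in stim.frequencies]] = False
        assert spec[mask].max() < 1e-6  # no leakage off the tone bins

    def test_empty_tone_list_composes_silence(self):
        stim = em.StimulusSet(())
        assert np.all(em.compose_stimulus(stim) == 0)

    def test_zero_epoch_flags_below_floor(self):
        stim = em.default_stimulus()
        ests = em.extract_cm(_epoch_of(np.zeros(22050)), stim, noise_floor_uv=0.05)
        assert all(e.amplitude == 0 and e.phase == 0 and e.below_floor for e in ests)

    def test_misaligned_frequency_rejected(self):
        stim = em.StimulusSet((em.ToneSpec(507.0),), epoch_duration=1.0)
        with pytest.raises(ValueError):
            em.extract_cm(em.EpochRecord(np.zeros(22050 // 2), 22050.0, 0.0), stim)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_fft_agrees_with_quadrature_oracle(self, seed):
        """FFT extraction equals independent quadrature demodulation to 1e-9
        relative on noiseless random 4-tone epochs."""
        rng = np.random.default_rng(seed)
        stim = em.default_stimulus()
        amps = rng.uniform(0.5, 20.0, 4)
        phases = rng.uniform(-math.pi, math.pi, 4)
        t = np.arange(stim.n_epoch_samples) / stim.sample_rate
        wave = sum(
            a * np.cos(2 * np.pi * f * t + p)
            for f, a, p in zip(stim.frequencies, amps, phases)
        )
        ep = _epoch_of(wave)
        for est, a_true, p_true in zip(em.extract_cm(ep, stim), amps, phases):
            a_q, p_q = em.quadrature_demodulate(ep, est.frequency)
            assert est.amplitude == pytest.approx(a_q, rel=1e-9)
            assert em.wrap_phase(est.phase - p_q) == pytest.approx(0, abs=1e-9)
            assert est.amplitude == pytest.approx(a_true, rel=1e-9)
            assert em.wrap_phase(est.phase - p_true) == pytest.approx(0, abs=1e-9)

    def test_linearity_of_extraction(self):
        stim = em.default_stimulus()
        wave = em.compose_stimulus(stim, amplitudes=[1, 2, 3, 4])
        one = em.extract_cm(_epoch_of(wave), stim)
        two = em.extract_cm(_epoch_of(2 * wave), stim)
        for e1, e2 in zip(one, two):
            assert e2.amplitude == pytest.approx(2 * e1.amplitude, rel=1e-12)
            assert e2.phase == pytest.approx(e1.phase, abs=1e-12)


class TestBuildBundle:
    def test_constant_epochs_give_constant_tracings(self):
        stim = em.default_stimulus()
        wave = em.compose_stimulus(stim, amplitudes=[5, 5, 5, 5])
        epochs = [_epoch_of(wave, t0=float(i)) for i in range(10)]
        bundle = em.build_bundle(epochs, stim)
        assert bundle.n_frames == 10
        np.testing.assert_allclose(bundle.frame_times, np.arange(10) + 0.5)
        for tr in bundle.tracings:
            np.testing.assert_allclose(tr.amplitude, 5.0, rtol=1e-9)

    def test_empty_and_mismatched_epochs(self):
        stim = em.default_stimulus()
        assert em.build_bundle([], stim) is None
        wave = em.compose_stimulus(stim)
        with pytest.raises(ValueError, match="sample rate"):
            em.build_bundle(
                [_epoch_of(wave), em.EpochRecord(np.zeros(11025), 11025.0, 1.0)],
                stim,
            )

    def test_wav_round_trip(self, tmp_path):
        stim = em.default_stimulus()
        scen = em.panel_c_scenario()
        epochs = em.render_epochs(scen)
        em.write_epochs_wav(epochs, tmp_path / "run.wav")
        back = em.read_epochs_wav(tmp_path / "run.wav")
        assert len(back) == len(epochs)
        b1 = em.build_bundle(epochs, stim)
        b2 = em.build_bundle(back, stim)
        for f in stim.frequencies:
            np.testing.assert_allclose(
                b2.tracing(f).amplitude, b1.tracing(f).amplitude, rtol=1e-5
            )


class TestUnwrapAndSmooth:
    def test_unwrap_standard_step(self):
        out = em.unwrap_phase([0.0, 3.0, -3.0])
        np.testing.assert_allclose(out, [0.0, 3.0, -3.0 + 2 * math.pi])

    def test_unwrap_constant_is_identity(self):
        x = np.full(7, 1.2)
        np.testing.assert_array_equal(em.unwrap_phase(x), x)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 200))
    def test_unwrap_inverts_wrapping_for_small_steps(self, seed, n):
        rng = np.random.default_rng(seed)
        steps = rng.uniform(-math.pi + 1e-6, math.pi - 1e-6, n - 1)
        true = np.concatenate([[0.0], np.cumsum(steps)])
        rec = em.unwrap_phase(em.wrap_phase(true))
        np.testing.assert_allclose(rec - rec[0], true, atol=1e-9)

    def test_smoothing_window_one_is_identity(self):
        tr = make_tracing(507.0, [1, 5, 2, 8, 3])
        out = em.smooth_tracing(tr, 1)
        np.testing.assert_array_equal(out.amplitude, tr.amplitude)

    def test_smoothing_impulse_becomes_plateau(self):
        tr = make_tracing(507.0, [0, 0, 9.0, 0, 0])
        out = em.smooth_tracing(tr, 3)
        np.testing.assert_allclose(out.amplitude, [0, 3, 3, 3, 0])

    def test_smoothing_constant_unchanged_and_bad_window_rejected(self):
        tr = make_tracing(507.0, np.full(9, 4.2))
        np.testing.assert_allclose(em.smooth_tracing(tr, 5).amplitude, 4.2)
        with pytest.raises(ValueError):
            em.smooth_tracing(tr, 2)
        with pytest.raises(ValueError):
            em.smooth_tracing(tr, 0)
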