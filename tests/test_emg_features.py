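"""Filter chain fidelity and MAV/RMS/MF/MDF correctness vs brute-force oracles."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitmill import (
    EmgSegment,
    GaitSchedule,
    SampledSignal,
    bandpass,
    default_burst_spec,
    envelope,
    gen_emg,
    gen_gait,
    mav,
    mean_freq,
    median_freq,
    notch50,
    phase_features,
    psd,
    rms,
    segment_cycles,
)
from gaitmill.emg_features import PsdEstimate, preprocess

FS = 1000.0


def sine(freq, fs=FS, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return SampledSignal(amp * np.sin(2 * np.pi * freq * t), fs, "GL_aff")


def steady_amplitude(sig):
    """Sine amplitude (RMS * sqrt(2)) away from the filter transients."""
    n = len(sig)
    return np.sqrt(2) * np.std(sig.samples[n // 4 : 3 * n // 4])


class TestBandpass:
    def test_passband_center_unit_gain(self):
        out = bandpass(sine(100.0))
        assert steady_amplitude(out) == pytest.approx(1.0, rel=0.02)

    def test_sub_hertz_attenuated(self):
        out = bandpass(sine(0.5, dur=8.0))
        assert steady_amplitude(out) < 0.2

    def test_dc_removed(self):
        base = sine(100.0)
        shifted = base.with_samples(base.samples + 3.0)
        np.testing.assert_allclose(
            bandpass(shifted).samples, bandpass(base).samples, atol=0.01 * 3.0
        )

    def test_zero_phase_no_lag(self):
        # a band-limited burst must not shift under the zero-phase chain
        rng = np.random.default_rng(7)
        x = np.zeros(4000)
        burst = rng.normal(size=400)
        sos = sps.butter(4, (60, 150), btype="bandpass", fs=FS, output="sos")
        x[1800:2200] = sps.sosfiltfilt(sos, burst)
        sig = SampledSignal(x, FS, "GL_aff")
        y = preprocess(sig).samples
        lags = sps.correlation_lags(len(x), len(x))
        lag = lags[np.argmax(sps.correlate(y, x))]
        assert lag == 0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="[Nn]yquist|fs"):
            bandpass(SampledSignal(np.zeros(100), 400.0, "GL_aff"))


class TestNotch:
    def test_mains_sine_suppressed(self):
        out = notch50(sine(50.0, dur=8.0))
        assert steady_amplitude(out) <= 0.1

    def test_neighbours_pass(self):
        assert steady_amplitude(notch50(sine(30.0))) >= 0.89
        assert steady_amplitude(notch50(sine(80.0))) >= 0.89

    def test_zero_in_zero_out(self):
        out = notch50(SampledSignal(np.zeros(1000), FS, "GL_aff"))
        np.testing.assert_array_equal(out.samples, 0.0)


class TestEnvelope:
    def test_constant_maps_to_itself(self):
        out = envelope(SampledSignal(np.full(500, 2.5), FS, "GL_aff"))
        np.testing.assert_allclose(out.samples, 2.5, rtol=1e-12)

    def test_impulse_spreads_to_window(self):
        x = np.zeros(301)
        x[150] = 1.0
        out = envelope(SampledSignal(x, FS, "GL_aff"), tau=0.05)  # w = 50
        on = np.flatnonzero(out.samples > 0)
        assert on.size == 50
        np.testing.assert_allclose(out.samples[on], 1.0 / 50, rtol=1e-12)

    def test_matches_brute_force_interior(self, rng):
        x = rng.normal(size=600)
        w = 49  # odd window: tau = 0.049 s at 1 kHz
        out = envelope(SampledSignal(x, FS, "GL_aff"), tau=0.049).samples
        h = w // 2
        for i in range(h, 600 - h, 37):
            assert out[i] == pytest.approx(np.mean(np.abs(x[i - h : i + h + 1])), rel=1e-12)

    def test_commutes_with_positive_scaling(self, rng):
        x = rng.normal(size=400)
        a = 3.7
        e1 = envelope(SampledSignal(a * x, FS, "GL_aff")).samples
        e2 = a * envelope(SampledSignal(x, FS, "GL_aff")).samples
        np.testing.assert_allclose(e1, e2, rtol=1e-12)

    def test_sub_sample_window_rejected(self):
        with pytest.raises(ValueError):
            envelope(SampledSignal(np.ones(10), FS, "GL_aff"), tau=1e-4)


class TestAmplitudeIndices:
    def test_closed_forms(self):
        seg = EmgSegment(np.array([1.0, -1.0, 1.0, -1.0]), FS)
        assert mav(seg) == 1.0
        seg2 = EmgSegment(np.array([3.0, -4.0]), FS)
        assert rms(seg2) == pytest.approx(np.sqrt(25 / 2))
        zeros = EmgSegment(np.zeros(8), FS)
        assert mav(zeros) == 0.0

    def test_sine_rms_is_amplitude_over_root2(self):
        x = np.sin(2 * np.pi * np.arange(10000) / 100.0)  # integer periods
        assert rms(EmgSegment(x, FS)) == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_brute_force_oracle_and_power_mean_inequality(self, rng):
        for _ in range(200):
            x = rng.normal(scale=10.0 ** rng.integers(-2, 3), size=int(rng.integers(2, 400)))
            seg = EmgSegment(x, FS)
            m = sum(abs(v) for v in x) / len(x)
            r = (sum(v * v for v in x) / len(x)) ** 0.5
            assert mav(seg) == pytest.approx(m, rel=1e-12)
            assert rms(seg) == pytest.approx(r, rel=1e-12)
            assert mav(seg) <= rms(seg) + 1e-15

    def test_time_reversal_invariance(self, rng):
        x = np.asarray(rng.normal(size=256))
        fwd, rev = EmgSegment(x, FS), EmgSegment(x[::-1], FS)
        assert mav(fwd) == pytest.approx(mav(rev), rel=1e-12)
        assert rms(fwd) == pytest.approx(rms(rev), rel=1e-12)
        pf, pr = psd(fwd), psd(rev)
        assert mean_freq(pf) == pytest.approx(mean_freq(pr), rel=1e-9)
        assert median_freq(pf) == pytest.approx(median_freq(pr), rel=1e-9)


class TestSpectralIndices:
    def test_peak_at_tone_frequency(self):
        x = np.sin(2 * np.pi * 80.0 * np.arange(1000) / FS)
        p = psd(EmgSegment(x, FS))
        assert p.f[np.argmax(p.P)] == pytest.approx(80.0, abs=1.0)

    def test_integrated_psd_matches_variance(self, rng):
        # Parseval-style normalization contract on white noise
        ratios = []
        for _ in range(50):
            x = rng.normal(size=1024)
            p = psd(EmgSegment(x, FS))
            ratios.append(p.total_power() / np.var(x))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_zero_signal_zero_psd_and_domain_errors(self):
        p = psd(EmgSegment(np.zeros(64), FS))
        np.testing.assert_array_equal(p.P, 0.0)
        with pytest.raises(ValueError):
            mean_freq(p)
        with pytest.raises(ValueError):
            median_freq(p)
        with pytest.raises(ValueError):
            psd(EmgSegment(np.zeros(4), FS))

    def test_flat_psd_mean_and_median_at_quarter_fs(self):
        f = np.linspace(0, 500, 501)
        p = PsdEstimate(f=f, P=np.ones_like(f), fs=FS)
        assert mean_freq(p) == pytest.approx(250.0, rel=1e-12)
        assert median_freq(p) == pytest.approx(250.0, rel=1e-12)

    def test_two_equal_masses_interpolate_to_midpoint(self):
        f = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        p = PsdEstimate(f=f, P=np.array([0.0, 1.0, 0.0, 1.0, 0.0]), fs=400.0)
        assert median_freq(p) == pytest.approx(100.0)

    def test_weighted_mean_and_cumulative_oracles(self, rng):
        for _ in range(50):
            f = np.linspace(0, 500, int(rng.integers(16, 200)))
            P = rng.uniform(0.01, 1.0, f.size)
            p = PsdEstimate(f=f, P=P, fs=FS)
            mf_oracle = np.trapezoid(f * P, f) / np.trapezoid(P, f)
            assert mean_freq(p) == pytest.approx(mf_oracle, rel=1e-9)
            # brute-force cumulative scan agrees within one grid step
            cum = np.array(
                [np.trapezoid(P[: k + 1], f[: k + 1]) for k in range(f.size)]
            )
            half = cum[-1] / 2
            k = int(np.searchsorted(cum, half))
            step = f[1] - f[0]
            assert abs(median_freq(p) - f[k]) <= step + 1e-9


class TestPhaseFeatures:
    @pytest.fixture
    def gl_pipeline(self):
        schedule = GaitSchedule(1.2, 0.6, 12, jitter_sd=0.0, start=0.5)
        heel, toe, truth = gen_gait(schedule, fs=FS, seed=3)
        cycles = segment_cycles(truth)
        emg = gen_emg(truth, default_burst_spec(), fs=FS, seed=3, muscle="GL")
        return preprocess(emg), cycles

    def test_stance_burst_dominates_swing(self, gl_pipeline):
        clean, cycles = gl_pipeline
        feats = phase_features(clean, cycles, muscle="GL", side="affected")
        stance = feats[("GL", "affected", "stance")]
        swing = feats[("GL", "affected", "swing")]
        assert stance.mav > 5 * swing.mav
        assert stance.n_cycles == len(cycles)

    def test_amplitude_homogeneity(self, gl_pipeline):
        clean, cycles = gl_pipeline
        f1 = phase_features(clean, cycles, muscle="GL", side="affected")
        f2 = phase_features(clean.with_samples(2 * clean.samples), cycles,
                            muscle="GL", side="affected")
        for key in f1.entries:
            assert f2[key].mav == pytest.approx(2 * f1[key].mav, rel=1e-9)
            assert f2[key].rms == pytest.approx(2 * f1[key].rms, rel=1e-9)
            assert abs(f2[key].mf - f1[key].mf) < 0.5
            assert abs(f2[key].mdf - f1[key].mdf) < 0.5

    def test_band_separation_reflected_in_mdf(self):
        # stance bursts 60-150 Hz vs swing bursts 20-60 Hz
        from gaitmill.synth import Burst, EmgBurstSpec

        spec = EmgBurstSpec({
            ("GL", "stance"): Burst(1.0, (60.0, 150.0)),
            ("GL", "swing"): Burst(1.0, (20.0, 60.0)),
        })
        schedule = GaitSchedule(1.2, 0.6, 10, jitter_sd=0.0, start=0.5)
        wins = 0
        for seed in range(20):
            _, _, truth = gen_gait(schedule, fs=FS, seed=seed)
            cycles = segment_cycles(truth)
            clean = preprocess(gen_emg(truth, spec, fs=FS, seed=seed, muscle="GL"))
            feats = phase_features(clean, cycles, muscle="GL", side="affected")
            wins += feats[("GL", "affected", "stance")].mdf > feats[("GL", "affected", "swing")].mdf
        assert wins == 20

    def test_no_cycles_yields_empty_set(self, gl_pipeline):
        clean, _ = gl_pipeline
        feats = phase_features(clean, [], muscle="GL", side="affected")
        assert len(feats) == 0

    def test_feature_table_schema(self, gl_pipeline):
        clean, cycles = gl_pipeline
        tab = phase_features(clean, cycles, muscle="GL", side="affected").to_frame("s1")
        assert list(tab.columns) == [
            "session_id", "muscle", "side", "phase", "mav", "rms", "mf", "mdf", "n_cycles"
        ]
        assert (tab["mav"] <= tab["rms"]).all()
        assert ((tab["mf"] > 0) & (tab["mf"] < FS / 2)).all()
        assert ((tab["mdf"] > 0) & (tab["mdf"] < FS / 2)).all()
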