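import numpy as np
import pytest
from scipy import signal as sps

from thermovitals.irt_io import RoiTrack, ThermalSequence
from thermovitals.respiration import (
    FLAG_CLINICIAN,
    FLAG_GAP,
    MotionSignal,
    RespirationConfig,
    autocorrelation,
    bandpass,
    chest_motion_signal,
    estimate_rr,
    extract_rr,
    temporal_filter,
)
from thermovitals.synthetic import ChestConfig, ClinicianEvent, SceneConfig, generate_scene


def make_signal(values, fs=4.0):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return MotionSignal(
        values=values,
        timestamps=np.arange(n) / fs,
        flags=[set() for _ in range(n)],
        valid=np.ones(n, dtype=bool),
    )


class TestTemporalFilter:
    def test_constant_identity(self):
        grids = [np.full((5, 5), 2.5)] * 4
        prev, nxt = temporal_filter(grids)
        np.testing.assert_array_equal(prev, grids[0])
        np.testing.assert_array_equal(nxt, grids[0])

    def test_scalar_means(self):
        grids = [np.full((1, 1), v) for v in (1.0, 2.0, 3.0, 4.0)]
        prev, nxt = temporal_filter(grids)
        assert prev.item() == pytest.approx(2.0)
        assert nxt.item() == pytest.approx(3.0)

    def test_variance_reduction_one_third(self, rng):
        # mean of 3 i.i.d. frames has variance sigma^2 / 3
        sigma = 0.04
        grids = [rng.normal(0, sigma, (100, 100)) for _ in range(4)]
        prev, _ = temporal_filter(grids)
        ratio = np.var(prev) / sigma**2
        assert ratio == pytest.approx(1 / 3, rel=0.1)

    def test_wrong_buffer_length(self):
        with pytest.raises(ValueError):
            temporal_filter([np.zeros((2, 2))] * 3)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            temporal_filter([np.zeros((2, 2))] * 3 + [np.zeros((3, 2))])


class TestBandpass:
    def test_zero_signal(self):
        out = bandpass(make_signal(np.zeros(200)))
        assert np.allclose(out.values, 0.0)

    def test_inband_sine_preserved_within_3db(self):
        cfg = RespirationConfig()
        t = np.arange(960) / cfg.fs
        out = bandpass(make_signal(np.sin(2 * np.pi * 0.25 * t)), cfg)
        # compare against the analytic double-pass magnitude at 0.25 Hz
        sos = sps.butter(2, [0.15, 0.44], btype="bandpass", fs=4.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[2 * np.pi * 0.25 / 4.0])
        expected_amp = np.abs(h[0]) ** 2  # forward-backward squares the magnitude
        amp = np.percentile(np.abs(out.values[100:-100]), 99)
        assert amp == pytest.approx(expected_amp, rel=0.05)
        assert expected_amp > 10 ** (-3 / 20)  # within 3 dB of unity

    def test_dc_attenuated_40db(self):
        cfg = RespirationConfig()
        out = bandpass(make_signal(np.ones(960)), cfg)
        assert np.abs(out.values).max() < 10 ** (-40 / 20)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bandpass(make_signal(np.ones(10)))


class TestAutocorrelation:
    def test_r0_is_one(self, rng):
        acf = autocorrelation(make_signal(rng.normal(size=300)))
        assert acf[0] == pytest.approx(1.0)

    def test_sine_peaks_at_period_multiples(self):
        t = np.arange(960) / 4.0
        acf = autocorrelation(make_signal(np.sin(2 * np.pi * t / 4.0)))  # T = 16 samples
        for k in (16, 32):
            assert acf[k] > acf[k - 2] and acf[k] > acf[k + 2]

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            autocorrelation(make_signal(np.full(100, 3.0)))

    def test_white_noise_band_small(self):
        # 3/sqrt(n) bound holds for >= 95% of (seed, lag) draws
        n, fs = 960, 4.0
        k_lo, k_hi = 10, 26  # lags of the respiratory band at 4 Hz
        hits = total = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=n)
            acf = autocorrelation(make_signal(x))
            band = np.abs(acf[k_lo : k_hi + 1])
            hits += (band < 3 / np.sqrt(n)).sum()
            total += band.size
        assert hits / total >= 0.95


class TestEstimateRR:
    @pytest.mark.parametrize("freq,expected", [(0.25, 15.0), (1 / 3, 20.0)])
    def test_clean_sine(self, freq, expected):
        cfg = RespirationConfig()
        t = np.arange(960) / cfg.fs
        filtered = bandpass(make_signal(np.sin(2 * np.pi * freq * t)), cfg)
        est = estimate_rr(autocorrelation(filtered), cfg)
        assert est.valid
        assert est.rr_bpm == pytest.approx(expected, abs=0.5)
        assert 60 / est.peak_lag == pytest.approx(est.rr_bpm)
        assert cfg.band_low <= 1 / est.peak_lag <= cfg.band_high

    def test_white_noise_below_floor_invalid(self):
        cfg = RespirationConfig(peak_floor=0.5)
        x = np.random.default_rng(0).normal(size=960)
        filtered = bandpass(make_signal(x), cfg)
        est = estimate_rr(autocorrelation(filtered), cfg)
        assert not est.valid

    def test_no_peak_invalid(self):
        acf = np.exp(-np.arange(100) / 5.0)  # monotone decay, no local max
        est = estimate_rr(acf, RespirationConfig())
        assert not est.valid
        assert est.exclusion_reason == "no_inband_peak"


class TestChestMotionSignal:
    def test_static_chest_near_zero(self):
        cfg = SceneConfig(width=96, height=72, duration=30.0, seed=11,
                          chest=ChestConfig(amplitude_px=0.0))
        seq, truth = generate_scene(cfg)
        sig = chest_motion_signal(seq, truth.boxes)
        assert sig.values.std() < 0.05

    def test_oscillation_frequency_recovered(self, small_scene):
        _, seq, truth = small_scene
        sig = chest_motion_signal(seq, truth.boxes)
        assert sig.axis == "y"
        f = np.fft.rfftfreq(len(sig.values), 1 / 4.0)
        spec = np.abs(np.fft.rfft(sig.values - sig.values.mean()))
        assert f[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_clinician_overlap_flagged(self):
        cfg = SceneConfig(
            width=96, height=72, duration=40.0, seed=12,
            clinician_events=(ClinicianEvent(10.0, 20.0, overlap_chest=True),),
        )
        seq, truth = generate_scene(cfg)
        sig = chest_motion_signal(seq, truth.boxes)
        # samples within the event window carry the flag
        in_event = (sig.timestamps > 10.5) & (sig.timestamps < 19.5)
        assert all(FLAG_CLINICIAN in fl for fl, hit in zip(sig.flags, in_event) if hit)
        out_event = sig.timestamps < 9.0
        assert all(FLAG_CLINICIAN not in fl for fl, hit in zip(sig.flags, out_event) if hit)

    def test_short_gap_bridged_long_gap_invalidated(self, small_scene):
        _, seq, truth = small_scene
        entries = {i: list(truth.boxes.entries[i]) for i in truth.boxes.entries}
        for i in range(40, 42):  # 2-frame gap: bridged
            entries[i] = [b for b in entries[i] if b.label != "chest"]
        for i in range(80, 90):  # 10-frame gap: invalidated
            entries[i] = [b for b in entries[i] if b.label != "chest"]
        sig = chest_motion_signal(seq, RoiTrack(entries))
        t_bridged = (sig.timestamps >= 10.0) & (sig.timestamps <= 10.25)
        assert sig.valid[t_bridged].all()
        gap_region = (sig.timestamps >= 20.8) & (sig.timestamps <= 21.8)
        assert not sig.valid[gap_region].any()

    def test_too_few_frames(self):
        seq = ThermalSequence.from_array(np.zeros((3, 8, 8)) + 20.0, fps=4.0)
        with pytest.raises(ValueError):
            chest_motion_signal(seq, RoiTrack())


class TestExtractRR:
    def test_end_to_end_15bpm(self, small_scene):
        # short window (60 s) -> coarser but still within 1 bpm
        _, seq, truth = small_scene
        est = extract_rr(seq, truth.boxes, RespirationConfig(window_frames=240))
        assert est.valid
        assert est.rr_bpm == pytest.approx(15.0, abs=1.0)

    def test_zero_motion_invalid(self):
        cfg = SceneConfig(width=96, height=72, duration=60.0, seed=13,
                          chest=ChestConfig(amplitude_px=0.0))
        seq, truth = generate_scene(cfg)
        est = extract_rr(seq, truth.boxes, RespirationConfig(window_frames=240))
        assert not est.valid

    def test_heavy_occlusion_invalid(self):
        cfg = SceneConfig(
            width=96, height=72, duration=60.0, seed=14,
            clinician_events=(ClinicianEvent(0.0, 40.0, overlap_chest=True),),
        )
        seq, truth = generate_scene(cfg)
        est = extract_rr(seq, truth.boxes, RespirationConfig(window_frames=240))
        assert not est.valid
        assert est.exclusion_reason == FLAG_CLINICIAN
        assert est.overlap_fraction > 0.5

    def test_amplitude_invariance(self):
        rrs = []
        for amp in (0.5, 1.0, 2.0):
            cfg = SceneConfig(width=96, height=72, duration=120.0, seed=15,
                              chest=ChestConfig(rr_bpm=15.0, amplitude_px=amp))
            seq, truth = generate_scene(cfg)
            est = extract_rr(seq, truth.boxes, RespirationConfig(window_frames=480))
            assert est.valid
            rrs.append(est.rr_bpm)
        assert max(rrs) - min(rrs) < 0.2

    def test_harmonic_waveform_keeps_fundamental(self):
        cfg = SceneConfig(width=96, height=72, duration=120.0, seed=16,
                          chest=ChestConfig(rr_bpm=15.0, amplitude_px=1.0,
                                            waveform="sine+harmonic"))
        seq, truth = generate_scene(cfg)
        est = extract_rr(seq, truth.boxes, RespirationConfig(window_frames=480))
        assert est.valid
        assert est.rr_bpm == pytest.approx(15.0, abs=1.0)


class TestConfig:
    def test_band_validation(self):
        with pytest.raises(ValueError):
            RespirationConfig(band_low=0.5, band_high=0.4)
        with pytest.raises(ValueError):
            RespirationConfig(band_high=3.0)  # above Nyquist at fs=4

    def test_motion_axis_validation(self):
        with pytest.raises(ValueError):
            RespirationConfig(motion_axis="z")
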