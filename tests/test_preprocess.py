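"""Resampling, EMG/alpha exclusion and stage selection."""

import numpy as np
import pytest

from spindlecwt.errors import EmptySelectionError, UnsupportedError
from spindlecwt.io_formats import (ChannelRole, EEGRecording, ExclusionMask,
                                   Hypnogram, Stage)
from spindlecwt.preprocess import (alpha_exclusion_mask, emg_artifact_mask,
                                   extract_stage_signal, resample_100hz)


def _rec(data, fs=250.0, label="C3A2"):
    return EEGRecording([label], [ChannelRole.CENTRAL], fs, np.atleast_2d(data))


class TestResample:
    def test_250_to_100_sample_count(self):
        rec = resample_100hz(_rec(np.zeros(250 * 60)))
        assert rec.fs == 100.0
        assert rec.n_samples == 6000

    def test_100hz_identity(self):
        rec = _rec(np.arange(1000.0), fs=100.0)
        assert resample_100hz(rec) is rec

    def test_below_100hz_unsupported(self):
        with pytest.raises(UnsupportedError):
            resample_100hz(_rec(np.zeros(100), fs=10.0))

    def test_sinusoid_amplitude_preserved(self):
        t250 = np.arange(250 * 20) / 250.0
        rec = resample_100hz(_rec(10.0 * np.sin(2 * np.pi * 10 * t250)))
        t100 = np.arange(rec.n_samples) / 100.0
        expected = 10.0 * np.sin(2 * np.pi * 10 * t100)
        core = slice(200, -200)  # skip filter edges
        assert np.allclose(rec.data[0][core], expected[core], atol=0.1)


class TestEmgMask:
    def test_zero_signal_empty_mask(self):
        m = emg_artifact_mask(np.zeros(3000), 100.0)
        assert m.masked_seconds() == 0.0

    def test_grid_aligned_burst_masks_exactly_seven_seconds(self):
        fs = 100
        x = np.zeros(60 * fs)
        t = np.arange(fs) / fs
        # 30 Hz, amplitude 11.3 uV -> in-band std 8 uV, one full window
        x[20 * fs:21 * fs] = 11.3 * np.sin(2 * np.pi * 30 * t)
        m = emg_artifact_mask(x, fs)
        assert m.masked_seconds() == pytest.approx(7.0)
        assert m.flags[17 * fs:24 * fs].all()

    def test_subthreshold_stationary_noise_unmasked(self):
        # in-band noise with std 5.0 < 5.75: direct rolling-std oracle agrees
        rng = np.random.default_rng(0)
        fs = 100
        from spindlecwt._filters import bandpass

        x = bandpass(rng.standard_normal(60 * fs), fs, 19.8, 45.5)
        filt = bandpass(x, fs, 19.8, 45.5)
        worst = max(filt[s:s + fs].std() for s in range(0, len(x) - fs + 1, fs // 2))
        x *= 5.5 / worst  # overall std ~5 uV, no window's std reaches 5.75
        filt = bandpass(x, fs, 19.8, 45.5)
        oracle = max(filt[s:s + fs].std() for s in range(0, len(x) - fs + 1, fs // 2))
        assert oracle < 5.75
        assert emg_artifact_mask(x, fs).masked_seconds() == 0.0

    def test_mask_monotone_in_artifact_amplitude(self):
        fs = 100
        t = np.arange(2 * fs) / fs
        base = np.zeros(120 * fs)
        base[50 * fs:52 * fs] = np.sin(2 * np.pi * 30 * t)
        small = emg_artifact_mask(10.0 * base, fs).flags
        large = emg_artifact_mask(30.0 * base, fs).flags
        assert np.all(large[small])  # scaling up never shrinks the masked set


class TestAlphaMask:
    def test_pure_delta_unmasked(self):
        fs = 100
        t = np.arange(60 * fs) / fs
        m = alpha_exclusion_mask(10 * np.sin(2 * np.pi * 3 * t), fs)
        assert m.masked_seconds() == 0.0

    def test_embedded_alpha_segment_masked(self):
        fs = 100
        t = np.arange(60 * fs) / fs
        x = 5 * np.sin(2 * np.pi * 3 * t)
        x[15 * fs:45 * fs] += 15 * np.sin(2 * np.pi * 10 * t[15 * fs:45 * fs])
        m, prof = alpha_exclusion_mask(x, fs, return_profile=True)
        assert m.flags[25 * fs:40 * fs].all()  # central >= 15 s covered
        assert m.masked_seconds() >= 15.0
        # oracle: direct per-second FFT band means agree with the profile
        from scipy.signal.windows import hann

        k = 30  # second inside the alpha segment
        win = hann(4 * fs, sym=False)
        spec = 2 * np.abs(np.fft.rfft(x[k * fs:k * fs + 4 * fs] * win)) / win.sum()
        freqs = np.fft.rfftfreq(4 * fs, 1 / fs)
        alpha_oracle = spec[(freqs >= 8) & (freqs <= 12)].mean()
        # high-pass at 1.4 Hz barely touches the 8-12 band
        assert prof.alpha[k] == pytest.approx(alpha_oracle, rel=0.05)

    def test_alpha_equal_to_delta_not_masked(self):
        # equality never exceeds the strict 1.1 factor
        fs = 100
        t = np.arange(60 * fs) / fs
        x = 8 * np.sin(2 * np.pi * 3 * t) + 8 * np.sin(2 * np.pi * 10 * t)
        m, prof = alpha_exclusion_mask(x, fs, return_profile=True)
        assert np.all(prof.alpha_activity <= 1.1 * prof.delta_activity)
        assert m.masked_seconds() == 0.0


class TestStageSelection:
    def test_all_s2_no_masks_single_segment(self):
        rec = _rec(np.arange(6000.0), fs=100.0)
        hyp = Hypnogram([Stage.S2, Stage.S2])
        clean = extract_stage_signal(rec, hyp, {Stage.S2})
        segs = clean.segments["C3A2"]
        assert len(segs) == 1 and segs[0].duration == 60.0

    def test_alternating_epochs_select_s2_only(self):
        rec = _rec(np.zeros(100 * 120), fs=100.0)
        hyp = Hypnogram([Stage.S2, Stage.REM, Stage.S2, Stage.REM])
        clean = extract_stage_signal(rec, hyp, {Stage.S2})
        segs = clean.segments["C3A2"]
        assert [(s.t0, s.duration) for s in segs] == [(0.0, 30.0), (60.0, 30.0)]

    def test_central_mask_splits_epoch(self):
        fs = 100
        rec = _rec(np.zeros(30 * fs), fs=100.0)
        hyp = Hypnogram([Stage.S2])
        flags = np.zeros(30 * fs, dtype=bool)
        flags[11 * fs:18 * fs] = True  # 7-s central mask
        masks = {"C3A2": ExclusionMask(100.0, flags)}
        clean = extract_stage_signal(rec, hyp, {Stage.S2}, masks)
        segs = clean.segments["C3A2"]
        assert len(segs) == 2
        assert sum(s.duration for s in segs) == pytest.approx(23.0)

    def test_clean_plus_masked_covers_recording(self):
        fs = 100
        n = 90 * fs
        rng = np.random.default_rng(1)
        rec = _rec(rng.normal(size=n), fs=100.0)
        hyp = Hypnogram([Stage.S2, Stage.REM, Stage.S2])
        flags = rng.random(n) < 0.1
        masks = {"C3A2": ExclusionMask(100.0, flags)}
        clean = extract_stage_signal(rec, hyp, {Stage.S2}, masks)
        clean_s = clean.total_seconds("C3A2")
        offstage_or_masked = np.sum(~(np.repeat([True, False, True], 30 * fs) & ~flags))
        assert clean_s + offstage_or_masked / fs == pytest.approx(90.0)

    def test_empty_selection_raises(self):
        rec = _rec(np.zeros(3000), fs=100.0)
        hyp = Hypnogram([Stage.REM])
        with pytest.raises(EmptySelectionError):
            extract_stage_signal(rec, hyp, {Stage.S2})
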