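"""Resampling to the 100 Hz working rate and artifact/alpha exclusion.

The detector works on a 100 Hz signal (0.01 s resolution).  Two exclusion
rules remove signal before anything else runs:

* **EMG artifacts** - the signal is band-passed to 19.8-45.5 Hz (-3 dB) and
  the standard deviation over 1-s windows (step 0.5 s) is compared with
  5.75 uV; every suprathreshold fragment is padded by 3 s on each side, so a
  single bad window removes 7 s of signal.
* **Alpha-dominated segments** - per-second mean spectral amplitudes in the
  delta (2-4 Hz) and alpha (8-12 Hz) bands are compared in a Hann-weighted
  15-s sliding window; a window with alpha_activity > 1.1 x delta_activity is
  excluded, because strings of alpha waves mimic sigma bursts.

Both rules run on the whole channel; stage selection intersects them later.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from ._filters import bandpass, highpass
from .errors import EmptySelectionError, UnsupportedError
from .io_formats import EEGRecording, ExclusionMask, Hypnogram, MaskReason

WORK_FS = 100.0


def resample_100hz(rec: EEGRecording) -> EEGRecording:
    """Anti-aliased polyphase resampling to 100 Hz.

    A 100 Hz recording is returned unchanged.  Rates below 100 Hz raise
    :class:`UnsupportedError`.
    """
    if rec.fs == WORK_FS:
        return rec
    if rec.fs < WORK_FS:
        raise UnsupportedError(f"sampling rate {rec.fs} Hz below the 100 Hz working rate")
    frac = Fraction(WORK_FS / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(list(rec.channel_labels), list(rec.channel_role),
                        WORK_FS, data, rec.start_time)


# ---------------------------------------------------------------------------
# EMG artifact exclusion
# ---------------------------------------------------------------------------

def emg_artifact_mask(x: np.ndarray, fs: float = WORK_FS, *,
                      threshold: float = 5.75, band=(19.8, 45.5),
                      window: float = 1.0, step: float = 0.5,
                      pad: float = 3.0) -> ExclusionMask:
    """Mask fragments with high-frequency muscle contamination.

    Windows anchored at t=0; trailing partial windows are dropped.  The
    exceedance fragment is the union of all suprathreshold windows; each
    contiguous fragment is padded by ``pad`` seconds on both sides and the
    result is clipped to the signal bounds.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    wlen, wstep = int(round(window * fs)), int(round(step * fs))
    if n >= wlen:
        filt = bandpass(x, fs, band[0], band[1])
        starts = np.arange(0, n - wlen + 1, wstep)
        views = np.lib.stride_tricks.sliding_window_view(filt, wlen)[starts]
        stds = views.std(axis=1)
        for s in starts[stds > threshold]:
            flags[s:s + wlen] = True
        flags = _pad_runs(flags, int(round(pad * fs)))
    reason = np.where(flags, MaskReason.EMG, MaskReason.NONE).astype(np.uint8)
    return ExclusionMask(fs, flags, reason)


def _pad_runs(flags: np.ndarray, pad: int) -> np.ndarray:
    out = flags.copy()
    for s, e in _runs(flags):
        out[max(0, s - pad):min(len(flags), e + pad)] = True
    return out


def _runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    return list(zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]))


# ---------------------------------------------------------------------------
# alpha exclusion
# ---------------------------------------------------------------------------

@dataclass
class AlphaDeltaProfile:
    """Per-second band amplitudes and the derived 15-s window activities."""

    delta: np.ndarray          # per-second mean 2-4 Hz amplitude, uV
    alpha: np.ndarray          # per-second mean 8-12 Hz amplitude, uV
    delta_activity: np.ndarray  # per 15-s window, Hann-weighted mean
    alpha_activity: np.ndarray


def alpha_exclusion_mask(x: np.ndarray, fs: float = WORK_FS, *,
                         ratio: float = 1.1, fft_window: float = 4.0,
                         compare_window: int = 15,
                         return_profile: bool = False):
    """Mask 15-s fragments dominated by alpha activity.

    The signal is high-pass filtered (-3 dB at 1.4 Hz); amplitude spectra are
    computed on 4-s Hann windows (step 1 s) and the mean amplitude in the
    delta (2-4 Hz) and alpha (8-12 Hz) bands is stored per second.  A 15-s
    sliding window (step 1 s) Hann-weights the 15 per-band values; the whole
    window is masked when alpha_activity > ``ratio`` x delta_activity
    (strict).  Overlapping triggering windows are unioned.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    flags = np.zeros(n, dtype=bool)
    nfft = int(round(fft_window * fs))
    step = int(round(fs))
    empty = AlphaDeltaProfile(*(np.empty(0),) * 4)
    if n < compare_window * fs:
        mask = ExclusionMask(fs, flags, np.zeros(n, dtype=np.uint8))
        return (mask, empty) if return_profile else mask

    filt = highpass(x, fs, 1.4)
    starts = np.arange(0, n - nfft + 1, step)
    win = sps.windows.hann(nfft, sym=False)
    frames = np.lib.stride_tricks.sliding_window_view(filt, nfft)[starts] * win
    spec = 2.0 * np.abs(np.fft.rfft(frames, axis=1)) / win.sum()
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    delta = spec[:, (freqs >= 2.0) & (freqs <= 4.0)].mean(axis=1)
    alpha = spec[:, (freqs >= 8.0) & (freqs <= 12.0)].mean(axis=1)

    m = delta.size
    w15 = sps.windows.hann(compare_window, sym=True)
    wsum = w15.sum()
    n_win = m - compare_window + 1
    alpha_act = np.empty(max(n_win, 0))
    delta_act = np.empty(max(n_win, 0))
    for j in range(n_win):
        sl = slice(j, j + compare_window)
        alpha_act[j] = np.dot(w15, alpha[sl]) / wsum
        delta_act[j] = np.dot(w15, delta[sl]) / wsum
        if alpha_act[j] > ratio * delta_act[j]:
            s = int(j * fs)
            flags[s:s + int(compare_window * fs)] = True
    reason = np.where(flags, MaskReason.ALPHA, MaskReason.NONE).astype(np.uint8)
    mask = ExclusionMask(fs, flags, reason)
    if return_profile:
        return mask, AlphaDeltaProfile(delta, alpha, delta_act, alpha_act)
    return mask


# ---------------------------------------------------------------------------
# stage selection
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """Contiguous clean signal with its position in recording time."""

    start: int          # sample index at the working rate
    data: np.ndarray
    fs: float = WORK_FS

    @property
    def t0(self) -> float:
        return self.start / self.fs

    @property
    def duration(self) -> float:
        return self.data.size / self.fs


@dataclass
class CleanSignal:
    """Per-channel clean segments: 'the signal chosen for spindle detection'."""

    segments: dict  # channel label -> list[Segment]

    def total_seconds(self, channel: str) -> float:
        return sum(s.duration for s in self.segments.get(channel, []))


def extract_stage_signal(rec: EEGRecording, hyp: Hypnogram, stages,
                         masks: dict | None = None) -> CleanSignal:
    """Maximal clean runs restricted to the requested sleep stages.

    ``masks`` maps channel label to :class:`ExclusionMask` (optional).
    Samples beyond hypnogram coverage (trailing partial epoch) are dropped.
    Raises :class:`EmptySelectionError` when nothing survives on any channel.
    """
    if rec.fs != WORK_FS:
        raise UnsupportedError("extract_stage_signal expects the 100 Hz working rate")
    stages = set(stages)
    n = rec.n_samples
    epoch_samples = int(round(hyp.epoch_length * rec.fs))
    stage_ok = np.zeros(n, dtype=bool)
    for i, s in enumerate(hyp.stages):
        if s in stages:
            a = i * epoch_samples
            stage_ok[a:min(a + epoch_samples, n)] = True

    out = {}
    total = 0.0
    for ch, row in zip(rec.channel_labels, rec.data):
        keep = stage_ok.copy()
        if masks and ch in masks:
            keep &= ~masks[ch].flags
        segs = [Segment(s, row[s:e].copy()) for s, e in _runs(keep)]
        out[ch] = segs
        total += sum(seg.duration for seg in segs)
    if total == 0:
        raise EmptySelectionError("no samples survive the stage/mask selection")
    return CleanSignal(out)
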