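"""Spindle scoring: all/slow/fast classification, measurement, summaries.

Scoring works on three band envelopes: ``cwt_slow`` and ``cwt_fast`` are the
pointwise maxima of the CWT magnitude over the slow and fast band's 0.1 Hz
grid, ``cwt_all`` their pointwise maximum, and ``cwt_stop`` the envelope at
the single ``stop_detect`` frequency, used as a rejection reference for
event classes that can be confused with slower activity:

* *all* spindles: events of ``cwt_all`` kept iff mean(cwt_all) over the
  event exceeds mean(cwt_stop);
* *fast* spindles: maximal runs where ``cwt_fast`` is continuously (strictly)
  above ``cwt_slow`` and above SA, kept with the usual duration/peak rules -
  no stop_detect test;
* *slow* spindles: the mirror-image of fast, plus the stop_detect test.

Fast and slow events can therefore never overlap in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._filters import bandpass
from .band_adjust import SpindleBands
from .cwt_core import cwt_magnitude, runs_above
from .errors import UnsupportedError, ValidationError
from .io_formats import Hypnogram, SpindleType
from .thresholds import DetectionThresholds


@dataclass
class BandEnvelopes:
    """Pointwise-max CWT magnitudes for the slow/fast bands and stop_detect."""

    fs: float
    cwt_slow: np.ndarray
    cwt_fast: np.ndarray
    cwt_stop: np.ndarray

    @property
    def cwt_all(self) -> np.ndarray:
        return np.maximum(self.cwt_slow, self.cwt_fast)


def band_envelopes(segment: np.ndarray, bands: SpindleBands, *,
                   f0: float = 2.0, fs: float = 100.0,
                   grid_step: float = 0.1) -> BandEnvelopes:
    """Compute the three band envelopes on a 0.1 Hz grid (endpoints inclusive)."""
    slow_freqs = np.round(np.arange(bands.slow[0], bands.slow[1] + 1e-9, grid_step), 3)
    fast_freqs = np.round(np.arange(bands.fast[0], bands.fast[1] + 1e-9, grid_step), 3)
    env_slow = cwt_magnitude(segment, slow_freqs, f0=f0, fs=fs).values.max(axis=0)
    env_fast = cwt_magnitude(segment, fast_freqs, f0=f0, fs=fs).values.max(axis=0)
    env_stop = cwt_magnitude(segment, [bands.stop_detect], f0=f0, fs=fs).values[0]
    return BandEnvelopes(fs=fs, cwt_slow=env_slow, cwt_fast=env_fast, cwt_stop=env_stop)


def _two_threshold_runs(values: np.ndarray, gate: np.ndarray, thr: DetectionThresholds,
                        fs: float, min_duration: float):
    """Maximal runs of ``gate`` meeting the duration and SP-peak criteria."""
    min_samples = int(round(min_duration * fs))
    d = np.diff(gate.astype(np.int8), prepend=0, append=0)
    out = []
    for s, e in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        if e - s >= min_samples and values[s:e].max() > thr.SP:
            out.append((s, e))
    return out


def score_all(env: BandEnvelopes, thr: DetectionThresholds,
              min_duration: float = 0.5):
    """All-spindle events: cwt_all criteria plus the stop_detect mean test."""
    values = env.cwt_all
    out = []
    for s, e in _two_threshold_runs(values, values > thr.SA, thr, env.fs, min_duration):
        if values[s:e].mean() > env.cwt_stop[s:e].mean():
            out.append((s / env.fs, e / env.fs))
    return out


def score_fast(env: BandEnvelopes, thr: DetectionThresholds,
               min_duration: float = 0.5):
    """Fast-spindle events: cwt_fast continuously above cwt_slow and above SA."""
    gate = (env.cwt_fast > env.cwt_slow) & (env.cwt_fast > thr.SA)
    runs = _two_threshold_runs(env.cwt_fast, gate, thr, env.fs, min_duration)
    return [(s / env.fs, e / env.fs) for s, e in runs]


def score_slow(env: BandEnvelopes, thr: DetectionThresholds,
               min_duration: float = 0.5):
    """Slow-spindle events: mirror of fast, plus the stop_detect mean test."""
    gate = (env.cwt_slow > env.cwt_fast) & (env.cwt_slow > thr.SA)
    out = []
    for s, e in _two_threshold_runs(env.cwt_slow, gate, thr, env.fs, min_duration):
        if env.cwt_slow[s:e].mean() > env.cwt_stop[s:e].mean():
            out.append((s / env.fs, e / env.fs))
    return out


def measure_event(segment: np.ndarray, onset: float, offset: float, *,
                  fs: float = 100.0, pad_to: float = 10.0,
                  band=(8.7, 18.5), search=(9.0, 16.0),
                  prefiltered: bool = False):
    """Spectral amplitude and dominant frequency of one event.

    The raw signal is band-pass filtered (-3 dB at 8.7 and 18.5 Hz), the
    event fragment is Hann-windowed, zero-padded to a 10 s window and
    Fourier-transformed, giving a 0.1 Hz frequency grid.  The height and
    location of the maximum spectral peak (within ``search``) are returned;
    the one-sided spectrum is scaled by 2/sum(hann) so a pure tone of
    amplitude A filling the fragment reports ~A.

    Set ``prefiltered=True`` when the segment has already been band-passed
    (e.g. once per channel in the pipeline).
    """
    if offset - onset > pad_to:
        raise UnsupportedError(f"event of {offset - onset:.1f} s exceeds the "
                               f"{pad_to} s analysis window")
    x = np.asarray(segment, dtype=float)
    if not prefiltered:
        x = bandpass(x, fs, band[0], band[1])
    s, e = int(round(onset * fs)), int(round(offset * fs))
    frag = x[s:e]
    if frag.size == 0 or not np.any(frag):
        raise ValidationError("event fragment is empty or all-zero: no spectral peak")
    win = sps.windows.hann(frag.size, sym=True)
    nfft = int(round(pad_to * fs))
    spec = 2.0 * np.abs(np.fft.rfft(frag * win, n=nfft)) / win.sum()
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    sel = np.nonzero((freqs >= search[0]) & (freqs <= search[1]))[0]
    k = sel[np.argmax(spec[sel])]
    return float(spec[k]), float(freqs[k])


def summarize(events, hypnogram: Hypnogram, stages) -> pd.DataFrame:
    """Per channel/stage/type spindle summary.

    Events are assigned to the epoch containing their onset.  ``density`` is
    spindles per 30-s epoch of the event's stage; ``activity`` is
    count x mean amplitude x mean duration.
    """
    stages = set(stages)
    rows = []
    for ev in events:
        if ev.stage is not None and ev.stage not in stages:
            continue
        rows.append({
            "channel": ev.channel,
            "stage": ev.stage.value if ev.stage else "",
            "type": ev.type.value,
            "duration": ev.duration,
            "amplitude": ev.amplitude,
            "frequency": ev.frequency,
        })
    epochs_by_stage = {s.value: hypnogram.count([s]) for s in stages}
    if not rows:
        return pd.DataFrame(columns=["channel", "stage", "type", "count", "density",
                                     "mean_duration", "mean_amplitude",
                                     "mean_frequency", "activity"])
    df = pd.DataFrame(rows)
    out = []
    for (ch, st, ty), grp in df.groupby(["channel", "stage", "type"]):
        n = len(grp)
        n_epochs = epochs_by_stage.get(st, 0)
        out.append({
            "channel": ch, "stage": st, "type": ty, "count": n,
            "density": n / n_epochs if n_epochs else np.nan,
            "mean_duration": grp["duration"].mean(),
            "mean_amplitude": grp["amplitude"].mean(),
            "mean_frequency": grp["frequency"].mean(),
            "activity": n * grp["amplitude"].mean() * grp["duration"].mean(),
        })
    return pd.DataFrame(out)
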