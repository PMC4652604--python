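"""Synthetic sleep EEG and twin phenotypes with known ground truth.

The generator emulates the signal classes the detector must separate:

* pink (1/f-amplitude) broadband background plus band-limited delta waves,
  the dominant power of NREM sleep EEG;
* waxing-waning sigma bursts (sleep spindles) with a Hann envelope - a slow
  train (default 11.5 Hz) weighted toward frontal channels and a fast train
  (default 13.5 Hz) weighted toward parietal channels;
* alpha bursts (8-12 Hz) that mimic spindle morphology and must be excluded;
* broadband EMG bursts (20-45 Hz) triggering the artifact rule.

Defaults are chosen to resemble C3/F3/P3 sleep EEG: total background SD
15 uV (delta-dominated; sigma-band RMS ~ 1.5-2 uV) and spindle envelope
peaks of 18 uV, an order of magnitude above the background sigma RMS, which
comfortably satisfies the >= 3x sigma-amplitude detectability condition.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._filters import bandpass
from .errors import GenerationError, ValidationError
from .io_formats import (ChannelRole, EEGRecording, Hypnogram, SpindleEvent,
                         SpindleType, Stage)


@dataclass
class SpindleTrainSpec:
    """One planted spindle population."""

    frequency: float                  # Hz
    density: float = 3.0              # expected spindles per 30-s epoch
    duration_range: tuple = (0.6, 1.4)  # s, uniform
    amplitude: float = 18.0           # envelope peak, uV
    #: per-role weight of this train's contribution to each channel
    channel_weights: dict = field(default_factory=dict)
    type: SpindleType = None

    def __post_init__(self):
        if self.type is None:
            self.type = SpindleType.SLOW if self.frequency < 13.0 else SpindleType.FAST


@dataclass
class BackgroundSpec:
    pink_sd: float = 15.0     # total SD of the 1/f background, uV
    delta_sd: float = 10.0    # SD of the extra 0.5-4 Hz component, uV


@dataclass
class BurstSpec:
    """Alpha or EMG burst population (rate in bursts per 30-s epoch)."""

    amplitude: float
    length: float
    rate: float
    frequency: float = None      # alpha carrier; None -> broadband noise
    band: tuple = (20.0, 45.0)   # EMG band when frequency is None


def _default_trains():
    return [
        SpindleTrainSpec(11.5, channel_weights={
            ChannelRole.FRONTAL: 1.0, ChannelRole.CENTRAL: 0.6, ChannelRole.PARIETAL: 0.2}),
        SpindleTrainSpec(13.5, channel_weights={
            ChannelRole.PARIETAL: 1.0, ChannelRole.CENTRAL: 0.6, ChannelRole.FRONTAL: 0.2}),
    ]


def _default_channels():
    return [("F3A2", ChannelRole.FRONTAL), ("P3A2", ChannelRole.PARIETAL)]


@dataclass
class SynthSpec:
    """Study conditions for one synthetic recording."""

    duration: float = 600.0
    fs: float = 250.0
    channels: list = field(default_factory=_default_channels)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    spindle_trains: list = field(default_factory=_default_trains)
    alpha_bursts: BurstSpec = field(
        default_factory=lambda: BurstSpec(amplitude=20.0, length=3.0, rate=0.2,
                                          frequency=10.0))
    emg_bursts: BurstSpec = field(
        default_factory=lambda: BurstSpec(amplitude=15.0, length=1.5, rate=0.1))
    hypnogram_plan: list = None      # stage per 30-s epoch; None -> all S2
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        for tr in self.spindle_trains:
            if tr.amplitude < 0:
                raise ValidationError("amplitudes must be >= 0")


def _pink_noise(rng, n, fs, sd):
    """1/f-amplitude noise via spectral shaping with random phase."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.maximum(freqs[nz], 0.5)
    phase = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(shape * phase, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _band_noise(rng, n, fs, lo, hi, sd):
    x = bandpass(rng.standard_normal(n), fs, lo, hi)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _plan_intervals(rng, n_epochs, epoch_len, rate, dur_lo, dur_hi, occupied,
                    max_tries=100):
    """Poisson-per-epoch event placement avoiding overlaps (0.5 s guard)."""
    out = []
    counts = rng.poisson(rate, size=n_epochs)
    for ep in range(n_epochs):
        for _ in range(counts[ep]):
            dur = float(rng.uniform(dur_lo, dur_hi))
            for attempt in range(max_tries):
                onset = ep * epoch_len + float(rng.uniform(0, max(epoch_len - dur, 1e-6)))
                iv = (onset - 0.5, onset + dur + 0.5)
                if all(iv[1] <= o[0] or iv[0] >= o[1] for o in occupied):
                    occupied.append((onset, onset + dur))
                    out.append((onset, dur))
                    break
            else:
                raise GenerationError(
                    "event density too high: cannot place bursts without overlap")
    return out


def generate_recording(spec: SynthSpec):
    """Synthesise a recording; returns (EEGRecording, ground_truth, Hypnogram).

    Ground truth lists one :class:`SpindleEvent` per planted spindle per
    channel whose role weight is positive, with the true onset/duration,
    carrier frequency and envelope-peak amplitude scaled by the role weight.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration * fs))
    n_epochs = max(1, int(spec.duration // 30.0))
    stages = list(spec.hypnogram_plan) if spec.hypnogram_plan else [Stage.S2] * n_epochs
    hyp = Hypnogram(stages)
    labels = [c[0] for c in spec.channels]
    roles = [c[1] if isinstance(c[1], ChannelRole) else ChannelRole(c[1])
             for c in spec.channels]
    t = np.arange(n) / fs

    data = np.zeros((len(labels), n))
    for i in range(len(labels)):
        data[i] += _pink_noise(rng, n, fs, spec.background.pink_sd)
        if spec.background.delta_sd > 0:
            data[i] += _band_noise(rng, n, fs, 0.5, 4.0, spec.background.delta_sd)

    occupied: list = []  # shared across trains: spindles never overlap
    ground_truth = []
    for train in spec.spindle_trains:
        events = _plan_intervals(rng, n_epochs, 30.0, train.density,
                                 *train.duration_range, occupied)
        for onset, dur in events:
            s = int(round(onset * fs))
            e = min(int(round((onset + dur) * fs)), n)
            if e - s < 2:
                continue
            seg_t = t[s:e]
            phase = rng.uniform(0, 2 * np.pi)
            env = sps.windows.hann(e - s, sym=True)
            wave = env * np.sin(2 * np.pi * train.frequency * seg_t + phase)
            for i, role in enumerate(roles):
                w = train.channel_weights.get(role, 0.0)
                if w > 0:
                    data[i, s:e] += train.amplitude * w * wave
                    ground_truth.append(SpindleEvent(
                        channel=labels[i], onset=onset, offset=onset + dur,
                        type=train.type, amplitude=train.amplitude * w,
                        frequency=train.frequency, stage=hyp.stage_at(onset)))

    # alpha bursts: spindle-like 8-12 Hz strings, stronger posteriorly
    ab = spec.alpha_bursts
    if ab is not None and ab.rate > 0 and ab.amplitude > 0:
        for onset, dur in _plan_intervals(rng, n_epochs, 30.0, ab.rate,
                                          ab.length, ab.length, occupied):
            s, e = int(round(onset * fs)), min(int(round((onset + dur) * fs)), n)
            env = sps.windows.hann(e - s, sym=True)
            wave = env * np.sin(2 * np.pi * ab.frequency * t[s:e] + rng.uniform(0, 2 * np.pi))
            for i, role in enumerate(roles):
                w = 1.0 if role in (ChannelRole.PARIETAL, ChannelRole.OTHER) else 0.7
                data[i, s:e] += ab.amplitude * w * wave

    eb = spec.emg_bursts
    if eb is not None and eb.rate > 0 and eb.amplitude > 0:
        for onset, dur in _plan_intervals(rng, n_epochs, 30.0, eb.rate,
                                          eb.length, eb.length, occupied):
            s, e = int(round(onset * fs)), min(int(round((onset + dur) * fs)), n)
            burst = _band_noise(rng, e - s, fs, eb.band[0], eb.band[1], eb.amplitude)
            burst *= sps.windows.tukey(e - s, 0.25)
            for i in range(len(labels)):
                data[i, s:e] += burst

    rec = EEGRecording(labels, roles, fs, data)
    ground_truth.sort(key=lambda ev: (ev.onset, ev.channel))
    return rec, ground_truth, hyp


# ---------------------------------------------------------------------------
# twin phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TwinSimSpec:
    """Additive-model twin phenotype simulation over two nights.

    MZ co-twins share the full genetic value; DZ co-twins' genetic values
    correlate 0.5.  The shared-environment value is common to a pair, the
    unique-environment value per subject, and night noise per subject-night.
    """

    n_mz: int = 32
    n_dz: int = 14
    mean: float = 4.0
    var_genetic: float = 0.8
    var_shared: float = 0.0
    var_unique: float = 0.2
    night_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for v in (self.var_genetic, self.var_shared, self.var_unique):
            if v < 0:
                raise ValidationError("variance components must be >= 0")


def generate_twin_dataset(spec: TwinSimSpec) -> pd.DataFrame:
    """Long-format table: pair_id, zygosity, member (a|b), night (1|2), value."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def emit(pair_id, zygosity, g_a, g_b):
        c = rng.normal(0, np.sqrt(spec.var_shared)) if spec.var_shared else 0.0
        for member, g in (("a", g_a), ("b", g_b)):
            u = rng.normal(0, np.sqrt(spec.var_unique)) if spec.var_unique else 0.0
            base = spec.mean + g + c + u
            for night in (1, 2):
                noise = rng.normal(0, spec.night_noise_sd) if spec.night_noise_sd else 0.0
                rows.append((pair_id, zygosity, member, night, base + noise))

    sg = np.sqrt(spec.var_genetic)
    for i in range(spec.n_mz):
        g = rng.normal(0, sg) if spec.var_genetic else 0.0
        emit(f"MZ{i:03d}", "MZ", g, g)
    half = np.sqrt(spec.var_genetic / 2.0)
    for i in range(spec.n_dz):
        if spec.var_genetic:
            common = rng.normal(0, half)
            g_a = common + rng.normal(0, half)
            g_b = common + rng.normal(0, half)
        else:
            g_a = g_b = 0.0
        emit(f"DZ{i:03d}", "DZ", g_a, g_b)

    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "member", "night", "value"])
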