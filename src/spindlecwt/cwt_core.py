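"""Complex Morlet wavelet, CWT magnitude envelopes and the event detector.

The mother wavelet is

    psi((t-b)/a) = pi**(-1/4) * exp(i 2 pi f0 (t-b)/a) * exp(-((t-b)/a)**2)

with central frequency parameter f0 = 2, whose two-cycle envelope closely
resembles a spindle.  The scale-to-frequency map is f = f0 / a; at f0 = 2 the
(omitted) Morlet correction term is negligible.  Kernels are L1-normalised so
that a unit-amplitude sinusoid at the kernel frequency yields a steady-state
CWT magnitude of ~1 in signal units, which makes the amplitude thresholds
behave uniformly across frequencies.

An event is a maximal run where the envelope strictly exceeds SA, kept iff it
lasts at least 0.5 s and the envelope strictly exceeds SP at least once
within it.  Ties break toward non-detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ShortSegmentError, ValidationError
from .thresholds import DetectionThresholds

DEFAULT_F0 = 2.0
#: envelope truncation: support ends where the Gaussian drops below 1e-6 of peak
_TRUNC = np.sqrt(np.log(1e6))


@dataclass
class MorletWavelet:
    """Sampled complex Morlet kernel at one frequency of interest."""

    freq: float
    f0: float
    fs: float
    t: np.ndarray
    kernel: np.ndarray  # L1-normalised: sum(|kernel|) * dt == 2

    @property
    def a(self) -> float:
        """Scale parameter; carrier frequency of the kernel is f0 / a."""
        return self.f0 / self.freq

    @property
    def support(self) -> float:
        """Kernel duration in seconds."""
        return self.t.size / self.fs


def morlet_kernel(freq: float, f0: float = DEFAULT_F0, fs: float = 100.0) -> MorletWavelet:
    """Sample the complex Morlet wavelet dilated to ``freq``.

    The symmetric support is truncated where the Gaussian envelope falls
    below 1e-6 of its peak.
    """
    if not 0 < freq < fs / 2:
        raise ValidationError(f"frequency {freq} Hz outside (0, {fs / 2})")
    a = f0 / freq
    half = int(np.ceil(_TRUNC * a * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / a
    psi = np.pi ** -0.25 * np.exp(2j * np.pi * f0 * u) * np.exp(-u ** 2)
    dt = 1.0 / fs
    psi *= 2.0 / (np.abs(psi).sum() * dt)
    return MorletWavelet(freq=freq, f0=f0, fs=fs, t=t, kernel=psi)


@dataclass
class Envelope:
    """|CWT| magnitude per sample for one or more frequencies of interest."""

    fs: float
    freqs: np.ndarray           # (n_freqs,)
    values: np.ndarray          # (n_freqs, n_samples), >= 0
    edge: np.ndarray = None     # bool (n_samples,), True inside the zero-padded edges

    def __post_init__(self):
        self.values = np.atleast_2d(self.values)
        self.freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if self.edge is None:
            self.edge = np.zeros(self.values.shape[1], dtype=bool)

    def at(self, freq: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.freqs - freq)))
        return self.values[i]


def cwt_magnitude(segment: np.ndarray, freqs, f0: float = DEFAULT_F0,
                  fs: float = 100.0) -> Envelope:
    """CWT magnitude of ``segment`` at each frequency in ``freqs``.

    Edges are computed with zero padding ('same' convolution) and flagged in
    ``Envelope.edge`` out to half the widest kernel support.
    """
    x = np.asarray(segment, dtype=float)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    kernels = [morlet_kernel(f, f0, fs) for f in freqs]
    max_len = max(k.kernel.size for k in kernels)
    if x.size < max_len:
        raise ShortSegmentError(
            f"segment of {x.size} samples shorter than the {max_len}-sample "
            f"kernel at {freqs.min():.1f} Hz")
    dt = 1.0 / fs
    values = np.empty((freqs.size, x.size))
    for i, k in enumerate(kernels):
        values[i] = np.abs(sps.oaconvolve(x, k.kernel, mode="same")) * dt
    edge = np.zeros(x.size, dtype=bool)
    half = max_len // 2
    edge[:half] = True
    edge[-half:] = True
    return Envelope(fs=fs, freqs=freqs, values=values, edge=edge)


def runs_above(values: np.ndarray, level: float):
    """Half-open index pairs of maximal runs where values > level (strict)."""
    above = values > level
    d = np.diff(above.astype(np.int8), prepend=0, append=0)
    return list(zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]))


def detect_events(env: np.ndarray | Envelope, thr: DetectionThresholds,
                  fs: float = 100.0, min_duration: float = 0.5):
    """Two-threshold event detection on a single envelope.

    Returns a list of ``(onset_s, offset_s)`` half-open intervals relative to
    the envelope start: maximal runs where env > SA, kept iff their duration
    is >= ``min_duration`` and max(env) > SP within the run.
    """
    if isinstance(env, Envelope):
        if env.values.shape[0] != 1:
            raise ValidationError("detect_events expects a single-frequency envelope")
        fs = env.fs
        values = env.values[0]
    else:
        values = np.asarray(env, dtype=float)
    min_samples = int(round(min_duration * fs))
    out = []
    for s, e in runs_above(values, thr.SA):
        if e - s >= min_samples and values[s:e].max() > thr.SP:
            out.append((s / fs, e / fs))
    return out
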