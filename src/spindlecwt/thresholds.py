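"""Background amplitude estimation and the two spindle detection thresholds.

The basic threshold BT summarises the background amplitude of the signal in
the 6-18 Hz range: amplitude spectra over non-overlapping 2-s windows are
log10-transformed, the per-bin median across windows estimates the background
(robust to transient bursts), and BT is the back-transformed mean of the
background bins.  The detection thresholds are fixed multiples of BT: the
spindle-activity threshold SA = 55 x BT must be exceeded for at least 0.5 s
and the spindle-peak threshold SP = 80 x BT at least once (SP/SA = 1.45).

The absolute scale of a windowed amplitude spectrum is conventional.  This
implementation scales spectra so that the 55x/80x multipliers place SA at
about twice the background sigma-band CWT envelope of EEG-like (1/f)
background - the operating point at which marginal detections sit just above
the background, with spectral spindle-to-background ratios near 1.2 (see
docs/methods.md).  The factor is exposed as ``spectrum_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import bandpass
from .errors import InsufficientDataError, ValidationError

#: calibration of the 2|X|/N one-sided amplitude spectrum; see module docstring
DEFAULT_SPECTRUM_SCALE = 0.10


@dataclass(frozen=True)
class DetectionThresholds:
    """Background amplitude BT and the derived SA/SP thresholds (uV scale)."""

    BT: float
    SA: float
    SP: float

    def __post_init__(self):
        if self.BT <= 0:
            raise ValidationError("BT must be positive")
        if not self.SA < self.SP:
            raise ValidationError("SA must be below SP")

    def scaled(self, factor: float) -> "DetectionThresholds":
        """Both thresholds scaled together (ratio preserved)."""
        return DetectionThresholds(self.BT * factor, self.SA * factor, self.SP * factor)


def basic_threshold(segments, fs: float = 100.0, *,
                    band=(5.5, 18.2), mean_range=(6.0, 18.0),
                    window: float = 2.0, min_duration: float = 60.0,
                    spectrum_scale: float = DEFAULT_SPECTRUM_SCALE) -> float:
    """Estimate the background amplitude BT from clean signal.

    Parameters
    ----------
    segments : list of 1-D arrays (clean signal pieces at ``fs``), or one
        array.  Windows never straddle segment boundaries; segments shorter
        than one window contribute nothing.
    min_duration : minimum total clean signal in seconds.

    Returns
    -------
    float
        BT in linear amplitude units: the back-transform (10**x) of the mean
        over 6-18 Hz bins of the per-bin median log10 amplitude.
    """
    if isinstance(segments, np.ndarray):
        segments = [segments]
    arrays = [np.asarray(s, dtype=float) for s in segments]
    total = sum(a.size for a in arrays) / fs
    if total < min_duration:
        raise InsufficientDataError(
            f"{total:.1f} s of clean signal, need >= {min_duration} s")

    nwin = int(round(window * fs))
    spectra = []
    for a in arrays:
        if a.size < nwin:
            continue
        filt = bandpass(a, fs, band[0], band[1])
        n_full = a.size // nwin
        frames = filt[:n_full * nwin].reshape(n_full, nwin)
        spectra.append(2.0 * np.abs(np.fft.rfft(frames, axis=1)) / nwin)
    if not spectra:
        raise InsufficientDataError("no segment long enough for a spectrum window")
    spec = np.vstack(spectra)
    freqs = np.fft.rfftfreq(nwin, 1.0 / fs)
    sel = (freqs >= mean_range[0]) & (freqs <= mean_range[1])
    spec = spec[:, sel]
    if np.any(spec <= 0):
        raise InsufficientDataError("degenerate (zero) spectrum; cannot log-transform")
    background = np.median(np.log10(spec), axis=0)  # per-bin median across windows
    return float(spectrum_scale * 10.0 ** background.mean())


def detection_thresholds(bt: float, *, sa_factor: float = 55.0,
                         sp_factor: float = 80.0) -> DetectionThresholds:
    """SA = 55 x BT and SP = 80 x BT."""
    if bt <= 0:
        raise ValidationError("BT must be positive")
    return DetectionThresholds(BT=bt, SA=sa_factor * bt, SP=sp_factor * bt)
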