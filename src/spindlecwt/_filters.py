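"""Linear-phase FIR filters with calibrated -3 dB edges.

All band edges in this package are specified as -3 dB (half-power) points.
``scipy.signal.firwin`` places the -6 dB point at its cutoff, so the cutoffs
are solved numerically until the measured -3 dB crossings of the designed
filter match the requested edges.  Filters are odd-length windowed-sinc
(Hamming) kernels applied with ``convolve(..., mode="same")``, i.e. zero
group delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

_CACHE: dict = {}

_SQRT_HALF = 1.0 / np.sqrt(2.0)


def _measured_3db(taps: np.ndarray, fs: float, target: float, rising: bool) -> float:
    """Frequency where |H| crosses 1/sqrt(2) nearest to ``target``."""
    w, h = signal.freqz(taps, worN=1 << 15, fs=fs)
    mag = np.abs(h)
    above = mag > _SQRT_HALF
    crossings = np.nonzero(above[1:] != above[:-1])[0]
    if crossings.size == 0:
        return np.nan
    # interpolate each crossing, pick the one closest to the target edge
    freqs = []
    for i in crossings:
        f0, f1 = w[i], w[i + 1]
        m0, m1 = mag[i], mag[i + 1]
        frac = (_SQRT_HALF - m0) / (m1 - m0)
        freqs.append(f0 + frac * (f1 - f0))
    freqs = np.asarray(freqs)
    return float(freqs[np.argmin(np.abs(freqs - target))])


def _design(fs: float, lo: float | None, hi: float | None, numtaps: int) -> np.ndarray:
    if lo is not None and hi is not None:
        cutoffs = [lo, hi]
        pass_zero = False
    elif lo is not None:
        cutoffs = [lo]
        pass_zero = False  # high-pass
    else:
        cutoffs = [hi]
        pass_zero = True  # low-pass
    taps = signal.firwin(numtaps, cutoffs, window="hamming", pass_zero=pass_zero, fs=fs)
    return taps


def fir_taps(fs: float, lo: float | None, hi: float | None, numtaps: int = 201) -> np.ndarray:
    """Return FIR taps whose measured -3 dB points sit at ``lo``/``hi``.

    Parameters
    ----------
    fs : sampling rate in Hz.
    lo, hi : requested -3 dB edges in Hz; ``None`` for a one-sided filter.
    numtaps : odd kernel length (controls transition width).
    """
    key = (round(fs, 6), lo, hi, numtaps)
    if key in _CACHE:
        return _CACHE[key]
    if numtaps % 2 == 0:
        numtaps += 1

    # Solve each edge's firwin cutoff by bisection; edges decouple because the
    # transition bands do not overlap for the bands used here.
    c_lo, c_hi = lo, hi
    for _ in range(3):  # alternate passes, converges fast
        if lo is not None:
            c_lo = _solve_edge(fs, lo, c_lo, c_hi, numtaps, which="lo")
        if hi is not None:
            c_hi = _solve_edge(fs, hi, c_lo, c_hi, numtaps, which="hi")
    taps = _design(fs, c_lo, c_hi, numtaps)
    _CACHE[key] = taps
    return taps


def _solve_edge(fs, target, c_lo, c_hi, numtaps, which):
    def measured(c):
        lo, hi = (c, c_hi) if which == "lo" else (c_lo, c)
        taps = _design(fs, lo, hi, numtaps)
        return _measured_3db(taps, fs, target, rising=(which == "lo"))

    # transition half-width of a Hamming windowed sinc, used to bracket
    span = max(0.5, 3.3 * fs / numtaps)
    a, b = max(target - span, 1e-3), min(target + span, fs / 2 - 1e-3)
    # keep the bracket strictly between the two cutoffs
    if which == "lo" and c_hi is not None:
        b = min(b, c_hi - 1e-2)
    if which == "hi" and c_lo is not None:
        a = max(a, c_lo + 1e-2)
    if a >= b:
        return target
    fa, fb = measured(a) - target, measured(b) - target
    if np.isnan(fa) or np.isnan(fb) or fa * fb > 0:
        return target  # fall back to nominal cutoff
    for _ in range(40):
        m = 0.5 * (a + b)
        fm = measured(m) - target
        if np.isnan(fm):
            break
        if fa * fm <= 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
        if b - a < 1e-4:
            break
    return 0.5 * (a + b)


def apply_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with zero group delay (odd taps, 'same')."""
    return signal.oaconvolve(x, taps, mode="same")


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
             numtaps: int | None = None) -> np.ndarray:
    if numtaps is None:
        # keep the Hamming transition width well below the lower band edge
        numtaps = min(max(201, int(6.6 * fs / lo) | 1), 8193)
    return apply_fir(x, fir_taps(fs, lo, hi, numtaps))


def highpass(x: np.ndarray, fs: float, lo: float, numtaps: int = 501) -> np.ndarray:
    return apply_fir(x, fir_taps(fs, lo, None, numtaps))
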