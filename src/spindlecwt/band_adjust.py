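"""Individual adjustment of slow and fast spindle frequency ranges.

Slow spindles predominate frontally and fast spindles parietally.  The
adjustment scans spindle events over a 9-16 Hz grid (0.1 Hz step, 71 bins)
on one frontal and one parietal channel, accumulates per-bin counts of
events whose CWT activity is dominant at that bin (``vec_slow`` from the
frontal channel, ``vec_fast`` from the parietal one), and compares the two
distributions through an antisymmetric relation vector ``vec_rel`` whose
minimum marks the slow-spindle centre and whose maximum seeds the
fast-spindle centre.  Band edges follow the curvature of the smoothed
parietal distribution (fast band) and the sign structure of ``vec_rel``
(slow band); ``stop_detect`` marks the highest frequency below the slow band
where parietal activity dominates, the reference used later to reject
non-spindle events.

With fewer than 30 accepted events in either vector the estimate is
unreliable and fixed fallback bands are returned instead (slow 11-12.9 Hz,
fast 13.1-15 Hz, stop_detect 9 Hz).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cwt_core import cwt_magnitude, detect_events
from .errors import ValidationError
from .preprocess import Segment
from .thresholds import DetectionThresholds

FREQ_GRID = np.round(np.arange(9.0, 16.0 + 1e-9, 0.1), 1)  # 71 bins
_SMOOTH_BINS = 7  # 0.7 Hz moving-average window on the 0.1 Hz grid


class BandSource(enum.Enum):
    ADJUSTED = "adjusted"
    FIXED_FALLBACK = "fixed_fallback"
    USER_FIXED = "user_fixed"


@dataclass
class SpindleBands:
    """Individually adjusted (or fixed) slow/fast spindle frequency ranges."""

    slow: tuple
    fast: tuple
    stop_detect: float
    slow_cntr: float = None
    fast_cntr: float = None
    source: BandSource = BandSource.ADJUSTED

    def __post_init__(self):
        if self.slow_cntr is None:
            self.slow_cntr = round(0.5 * (self.slow[0] + self.slow[1]), 2)
        if self.fast_cntr is None:
            self.fast_cntr = round(0.5 * (self.fast[0] + self.fast[1]), 2)
        self.validate()

    def validate(self):
        chain = (9.0 - 1e-9 <= self.stop_detect <= self.slow[0] + 1e-9
                 and self.slow[0] < self.slow[1] < self.fast[0] < self.fast[1] <= 16.0 + 1e-9)
        if not chain:
            raise ValidationError(
                f"band chain violated: stop={self.stop_detect}, slow={self.slow}, "
                f"fast={self.fast}")
        if self.slow[1] - self.slow[0] < 0.5 - 1e-9 or self.fast[1] - self.fast[0] < 0.5 - 1e-9:
            raise ValidationError("each band must be at least 0.5 Hz wide")


FALLBACK_BANDS = dict(slow=(11.0, 12.9), fast=(13.1, 15.0), stop_detect=9.0)


@dataclass
class ActivityScan:
    """Per-bin accepted-spindle counts from the frontal/parietal scan."""

    freq_grid: np.ndarray
    vec_slow: np.ndarray   # counts, frontal channel
    vec_fast: np.ndarray   # counts, parietal channel
    mean_act: float = None
    vec_rel: np.ndarray = None
    smooth_slow: np.ndarray = field(default=None, repr=False)
    smooth_fast: np.ndarray = field(default=None, repr=False)


def _segments(clean) -> list:
    if isinstance(clean, np.ndarray):
        return [Segment(0, np.asarray(clean, dtype=float))]
    return list(clean)


def _scan_channel(segments, thr: DetectionThresholds, f0: float, fs: float,
                  min_duration: float) -> np.ndarray:
    counts = np.zeros(FREQ_GRID.size)
    for seg in _segments(segments):
        x = seg.data if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
        try:
            env = cwt_magnitude(x, FREQ_GRID, f0=f0, fs=fs)
        except Exception:
            continue  # segment shorter than the 9 Hz kernel: nothing to scan
        csum = np.concatenate([np.zeros((FREQ_GRID.size, 1)), np.cumsum(env.values, axis=1)], axis=1)
        for i in range(FREQ_GRID.size):
            for on, off in detect_events(env.values[i], thr, fs=fs, min_duration=min_duration):
                s, e = int(round(on * fs)), int(round(off * fs))
                means = (csum[:, e] - csum[:, s]) / (e - s)
                # dominance: this bin's mean activity strictly exceeds every other
                others = np.delete(means, i)
                if means[i] > others.max():
                    counts[i] += 1
    return counts


def activity_scan(frontal_clean, parietal_clean,
                  thr_frontal: DetectionThresholds, thr_parietal: DetectionThresholds,
                  *, f0: float = 2.0, fs: float = 100.0,
                  min_duration: float = 0.5) -> ActivityScan:
    """Scan spindle events over the 71-bin grid on both channels.

    For every bin, events are detected on that bin's envelope with the
    channel's own thresholds; an event is counted for the bin iff its mean
    envelope at that bin strictly exceeds its mean envelope at every other
    bin.  Each detected event is therefore counted in at most one bin.
    """
    return ActivityScan(
        freq_grid=FREQ_GRID.copy(),
        vec_slow=_scan_channel(frontal_clean, thr_frontal, f0, fs, min_duration),
        vec_fast=_scan_channel(parietal_clean, thr_parietal, f0, fs, min_duration),
    )


def moving_average(v: np.ndarray, window: int = _SMOOTH_BINS) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    kernel = np.ones(window)
    return np.convolve(v, kernel, mode="same") / np.convolve(np.ones_like(v), kernel, mode="same")


def relation_vector(scan: ActivityScan) -> np.ndarray:
    """Antisymmetric frontal/parietal activity relation over the grid.

    The 9 Hz bin of both count vectors is zeroed (it aggregates everything at
    and below 9 Hz, where spindles are unlikely), both vectors are smoothed
    twice with a 0.7 Hz moving average, and half of the grand mean activity
    is added to both before forming the ratio, which keeps the relation
    finite and damps bins with very few spindles:

        rel[i] =  v_fast[i]/v_slow[i] - 1   where v_fast >= v_slow
        rel[i] = -(v_slow[i]/v_fast[i] - 1) otherwise

    followed by one more smoothing pass.  Positive values mean more parietal
    (fast) activity; swapping the channels negates the vector.
    """
    vs = scan.vec_slow.astype(float).copy()
    vf = scan.vec_fast.astype(float).copy()
    vs[0] = 0.0
    vf[0] = 0.0
    for _ in range(2):
        vs = moving_average(vs)
        vf = moving_average(vf)
    scan.smooth_slow, scan.smooth_fast = vs, vf
    mean_act = 0.5 * (vs.mean() + vf.mean())
    scan.mean_act = float(mean_act)
    if mean_act == 0:
        scan.vec_rel = np.zeros_like(vs)
        return scan.vec_rel
    dvs = vs + 0.5 * mean_act
    dvf = vf + 0.5 * mean_act
    rel = np.where(dvf >= dvs, dvf / dvs - 1.0, -(dvs / dvf - 1.0))
    scan.vec_rel = moving_average(rel)
    return scan.vec_rel


def _nearest_sign_change(d2: np.ndarray, start: int, direction: int) -> int | None:
    i = start
    while 0 <= i + direction < d2.size:
        if d2[i] == 0 or d2[i] * d2[i + direction] < 0:
            return i
        i += direction
    return None


def _local_max_near(v: np.ndarray, idx: int, radius: int) -> int:
    """Nearest local maximum of v within +-radius bins; ties -> lower frequency."""
    lo, hi = max(0, idx - radius), min(v.size - 1, idx + radius)
    candidates = []
    for i in range(lo, hi + 1):
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < v.size - 1 else -np.inf
        if v[i] >= left and v[i] >= right:
            candidates.append(i)
    if not candidates:
        return idx
    dist = [abs(i - idx) for i in candidates]
    best = min(zip(dist, candidates))  # ties resolve to the lower index
    return best[1]


def estimate_bands(scan: ActivityScan, *, min_spindles: int = 30,
                   rel_fraction: float = 0.6) -> SpindleBands:
    """Estimate slow/fast bands and stop_detect from an activity scan.

    Falls back to the fixed bands (slow 11-12.9, fast 13.1-15, stop 9) when
    either vector holds fewer than ``min_spindles`` accepted events (counted
    after the 9 Hz zeroing).  ``rel_fraction`` implements the "40 % higher
    than the minimum" rule for the slow band's lower edge: the edge is the
    first bin, descending from the slow centre, where vec_rel has recovered
    to ``rel_fraction`` x its (negative) minimum.
    """
    grid = scan.freq_grid
    n_slow = scan.vec_slow[1:].sum()
    n_fast = scan.vec_fast[1:].sum()
    if n_slow < min_spindles or n_fast < min_spindles:
        return SpindleBands(**FALLBACK_BANDS, source=BandSource.FIXED_FALLBACK)

    rel = relation_vector(scan)
    vs, vf = scan.smooth_slow, scan.smooth_fast

    i_slow = int(np.argmin(rel))
    tail = rel[i_slow + 1:]
    if tail.size == 0:
        return SpindleBands(**FALLBACK_BANDS, source=BandSource.FIXED_FALLBACK)
    i_fast_cand = i_slow + 1 + int(np.argmax(tail))
    i_fast = _local_max_near(vf, i_fast_cand, radius=10)  # +-1 Hz
    if i_fast <= i_slow:
        i_fast = i_fast_cand

    # fast band: zero crossings of the second derivative of smoothed vec_fast
    d2 = np.gradient(np.gradient(vf))
    lo = _nearest_sign_change(d2, i_fast, -1)
    hi = _nearest_sign_change(d2, i_fast, +1)
    i_fast_lo = lo if lo is not None else i_slow + 1
    i_fast_hi = hi if hi is not None else grid.size - 1
    i_fast_lo = max(i_fast_lo, i_slow + 1)

    # widen to the 0.5 Hz minimum around the centre
    i_fast_lo, i_fast_hi = _widen(i_fast_lo, i_fast_hi, i_fast, grid.size)

    # slow upper edge: highest bin below fast.lo with frontal dominance
    i_slow_hi = None
    for i in range(i_fast_lo - 1, i_slow - 1, -1):
        if vs[i] > vf[i]:
            i_slow_hi = i
            break
    if i_slow_hi is None or i_slow_hi <= i_slow:
        i_slow_hi = max(i_slow + 1, i_fast_lo - 1)

    # slow lower edge: descend until vec_rel recovers to rel_fraction x minimum
    level = rel_fraction * rel[i_slow]  # rel minimum is negative
    i_slow_lo = i_slow
    for i in range(i_slow, -1, -1):
        if rel[i] >= level:
            i_slow_lo = i
            break
        i_slow_lo = i
    i_slow_lo, i_slow_hi = _widen(i_slow_lo, i_slow_hi, i_slow, grid.size)
    i_slow_hi = min(i_slow_hi, i_fast_lo - 1)
    if i_slow_hi <= i_slow_lo:
        i_slow_lo = max(0, i_slow_hi - 5)

    # stop_detect: highest bin below slow.lo with parietal dominance, else 9 Hz
    i_stop = 0
    for i in range(i_slow_lo - 1, -1, -1):
        if vf[i] > vs[i]:
            i_stop = i
            break

    try:
        return SpindleBands(
            slow=(float(grid[i_slow_lo]), float(grid[i_slow_hi])),
            fast=(float(grid[i_fast_lo]), float(grid[i_fast_hi])),
            stop_detect=float(grid[i_stop]),
            slow_cntr=float(grid[i_slow]),
            fast_cntr=float(grid[i_fast]),
            source=BandSource.ADJUSTED,
        )
    except ValidationError:
        return SpindleBands(**FALLBACK_BANDS, source=BandSource.FIXED_FALLBACK)


def _widen(lo: int, hi: int, centre: int, n: int, min_bins: int = 5):
    """Symmetric widening around ``centre`` until the band spans >= 0.5 Hz."""
    while hi - lo < min_bins:
        grew = False
        if lo > 0 and (centre - lo <= hi - centre or hi == n - 1):
            lo -= 1
            grew = True
        elif hi < n - 1:
            hi += 1
            grew = True
        if not grew:
            break
    return lo, hi
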