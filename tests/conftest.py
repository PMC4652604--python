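"""Shared fixtures: synthetic recordings and a minimal EDF writer.

All fixture data is generated at test time; nothing binary ships with the
package.  The EDF writer below produces a minimal spec-conforming EDF header
plus int16 data records, enough for round-trip tests through the reader.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

from spindlecwt.io_formats import ChannelRole
from spindlecwt.synthgen import SpindleTrainSpec, SynthSpec, generate_recording


def write_minimal_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal EDF file (one data record per second, int16, uV)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_sig, n_samp = data.shape
    spr = int(round(fs))                      # samples per 1-s record
    n_rec = n_samp // spr
    data = data[:, :n_rec * spr]

    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_sig)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_sig), 4),
    ])
    fields = [
        (16, labels), (80, [""] * n_sig), (8, ["uV"] * n_sig),
        (8, [f"{phys_min}"] * n_sig), (8, [f"{phys_max}"] * n_sig),
        (8, [str(dig_min)] * n_sig), (8, [str(dig_max)] * n_sig),
        (80, [""] * n_sig), (8, [str(spr)] * n_sig), (32, [""] * n_sig),
    ]
    for width, values in fields:
        header += b"".join(pad(str(v), width) for v in values)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round(data * gain), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for s in range(n_sig):
                fh.write(digital[s, r * spr:(r + 1) * spr].tobytes())


@pytest.fixture(scope="session")
def default_recording():
    """Default 10-min synthetic recording with both spindle trains."""
    spec = SynthSpec(duration=600.0, seed=7)
    return generate_recording(spec)


def separated_trains_spec(seed=11, duration=600.0):
    """Slow train only frontal, fast train only parietal; no alpha/EMG.

    The condition of the detection-performance properties: well-separated
    trains whose envelope peak (18 uV) is far above the background
    sigma-band amplitude.
    """
    trains = [
        SpindleTrainSpec(11.5, channel_weights={ChannelRole.FRONTAL: 1.0}),
        SpindleTrainSpec(13.5, channel_weights={ChannelRole.PARIETAL: 1.0}),
    ]
    return SynthSpec(duration=duration, seed=seed, spindle_trains=trains,
                     alpha_bursts=None, emg_bursts=None)


@pytest.fixture(scope="session")
def separated_recording():
    return generate_recording(separated_trains_spec())


@pytest.fixture(scope="session")
def separated_scan(separated_recording):
    """Activity scan of the separated-trains recording (frontal vs parietal)."""
    from spindlecwt.band_adjust import activity_scan
    from spindlecwt.preprocess import extract_stage_signal, resample_100hz
    from spindlecwt.io_formats import Stage
    from spindlecwt.thresholds import basic_threshold, detection_thresholds

    rec, truth, hyp = separated_recording
    rec100 = resample_100hz(rec)
    clean = extract_stage_signal(rec100, hyp, {Stage.S2})
    thr = {ch: detection_thresholds(
        basic_threshold([s.data for s in clean.segments[ch]], rec100.fs))
        for ch in rec100.channel_labels}
    scan = activity_scan(clean.segments["F3A2"], clean.segments["P3A2"],
                         thr["F3A2"], thr["P3A2"])
    return scan


def overlap(a, b) -> float:
    """Temporal intersection of two (onset, offset) pairs or events."""
    a0, a1 = (a.onset, a.offset) if hasattr(a, "onset") else a
    b0, b1 = (b.onset, b.offset) if hasattr(b, "onset") else b
    return min(a1, b1) - max(a0, b0)
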