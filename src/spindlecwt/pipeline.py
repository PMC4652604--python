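"""End-to-end detection pipeline.

Stage order: artifact/alpha exclusion -> per-channel threshold -> band
adjustment (auto mode needs one frontal and one parietal channel) ->
scoring.  All intermediates (masks, thresholds, bands) are returned and
logged so that per-subject quantities can be inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._filters import bandpass
from .band_adjust import (ActivityScan, BandSource, SpindleBands, activity_scan,
                          estimate_bands)
from .config import RunConfig
from .errors import ConfigurationError, InsufficientDataError
from .io_formats import ChannelRole, EEGRecording, Hypnogram, SpindleEvent, SpindleType
from .preprocess import (CleanSignal, alpha_exclusion_mask, emg_artifact_mask,
                         extract_stage_signal, resample_100hz)
from .scoring import (band_envelopes, measure_event, score_all, score_fast,
                      score_slow, summarize)
from .thresholds import basic_threshold, detection_thresholds

log = logging.getLogger("spindlecwt")


@dataclass
class RunResult:
    events: list
    summary: pd.DataFrame
    bands: SpindleBands
    thresholds: dict          # channel -> DetectionThresholds
    masks: dict               # channel -> ExclusionMask
    scan: ActivityScan | None = None


def run_detection(config: RunConfig, recording: EEGRecording,
                  hypnogram: Hypnogram | None) -> RunResult:
    """Run the whole detection chain on one recording."""
    if hypnogram is None:
        raise ConfigurationError("a hypnogram is required")
    rec = resample_100hz(recording)
    if config.roles:
        roles = [config.role_map().get(lab, role)
                 for lab, role in zip(rec.channel_labels, rec.channel_role)]
        rec = EEGRecording(rec.channel_labels, roles, rec.fs, rec.data, rec.start_time)
    channels = config.channels or rec.channel_labels
    stages = config.stage_set()

    masks = {}
    for ch in channels:
        x = rec.channel(ch)
        m = (emg_artifact_mask(x, rec.fs, threshold=config.emg_threshold_uv,
                               pad=config.emg_pad_s)
             | alpha_exclusion_mask(x, rec.fs, ratio=config.alpha_ratio))
        masks[ch] = m
        log.info("channel %s: %.1f s masked (EMG %.1f s, alpha %.1f s)", ch,
                 m.masked_seconds(), m.masked_seconds(1), m.masked_seconds(2))

    clean = extract_stage_signal(rec, hypnogram, stages, masks)

    thresholds = {}
    for ch in channels:
        bt = basic_threshold([s.data for s in clean.segments[ch]], rec.fs,
                             min_duration=config.bt_min_clean_s,
                             spectrum_scale=config.bt_spectrum_scale)
        thresholds[ch] = detection_thresholds(bt, sa_factor=config.sa_factor,
                                              sp_factor=config.sp_factor)
        log.info("channel %s: BT=%.4f SA=%.3f SP=%.3f", ch, bt,
                 thresholds[ch].SA, thresholds[ch].SP)

    scan = None
    if config.band_mode == "auto":
        frontal = [c for c in channels
                   if rec.channel_role[rec.channel_labels.index(c)] == ChannelRole.FRONTAL]
        parietal = [c for c in channels
                    if rec.channel_role[rec.channel_labels.index(c)] == ChannelRole.PARIETAL]
        if not frontal or not parietal:
            raise ConfigurationError(
                "auto band adjustment needs one frontal and one parietal channel; "
                "use fixed bands (--bands fixed) for this montage")
        scan = activity_scan(clean.segments[frontal[0]], clean.segments[parietal[0]],
                             thresholds[frontal[0]], thresholds[parietal[0]],
                             f0=config.f0, fs=rec.fs,
                             min_duration=config.min_duration_s)
        bands = estimate_bands(scan, min_spindles=config.min_scan_spindles)
    else:
        bands = SpindleBands(config.fixed_slow, config.fixed_fast, config.fixed_stop,
                             source=BandSource.USER_FIXED)
    log.info("bands: slow %s fast %s stop %.1f (%s)", bands.slow, bands.fast,
             bands.stop_detect, bands.source.value)

    events = []
    for ch in channels:
        thr = thresholds[ch]
        filtered = bandpass(rec.channel(ch), rec.fs, 8.7, 18.5)
        for seg in clean.segments[ch]:
            try:
                env = band_envelopes(seg.data, bands, f0=config.f0, fs=rec.fs)
            except Exception:
                continue  # segment shorter than the widest kernel
            for stype, scored in ((SpindleType.ALL, score_all(env, thr, config.min_duration_s)),
                                  (SpindleType.FAST, score_fast(env, thr, config.min_duration_s)),
                                  (SpindleType.SLOW, score_slow(env, thr, config.min_duration_s))):
                for on, off in scored:
                    g_on, g_off = seg.t0 + on, seg.t0 + off
                    amp, freq = measure_event(filtered, g_on, g_off, fs=rec.fs,
                                              prefiltered=True)
                    events.append(SpindleEvent(
                        channel=ch, onset=g_on, offset=g_off, type=stype,
                        amplitude=amp, frequency=freq,
                        stage=hypnogram.stage_at(g_on)))

    events.sort(key=lambda ev: (ev.channel, ev.onset))
    summary = summarize(events, hypnogram, stages)
    return RunResult(events=events, summary=summary, bands=bands,
                     thresholds=thresholds, masks=masks, scan=scan)
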