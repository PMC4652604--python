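"""Agreement statistics between two spindle scorings.

Scorings are compared on a common 0.1-s binary timeline: a bin is positive
for a scorer iff any of its events overlaps the bin.  Because most sleep EEG
contains no spindles, the negative class dominates; besides sensitivity /
specificity / precision the chance- and imbalance-corrected statistics are
reported: Cohen's kappa, the Matthews correlation coefficient (identical to
the Pearson correlation of the two binary timelines) and the adjusted
geometric mean of Batuwita & Palade.  Event-level consensus uses a minimum
0.3-s overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .io_formats import Hypnogram


@dataclass
class AgreementResult:
    """Confusion counts on 0.1-s bins (A is the reference) and statistics."""

    TP: int
    FP: int
    FN: int
    TN: int
    sensitivity: float
    specificity: float
    precision: float
    kappa: float
    adjusted_gmean: float
    matthews: float
    kappa_label: str


def _interval(ev):
    """(onset, offset) from a SpindleEvent or a plain pair."""
    if hasattr(ev, "onset"):
        return float(ev.onset), float(ev.offset)
    return float(ev[0]), float(ev[1])


def binarize_timeline(events, duration: float, resolution: float = 0.1) -> np.ndarray:
    """Boolean vector over ``[0, duration)``; bin true iff any event overlaps it."""
    n = int(round(duration / resolution))
    out = np.zeros(n, dtype=bool)
    for ev in events:
        on, off = _interval(ev)
        a = max(0, int(np.floor(on / resolution + 1e-9)))
        b = min(n, int(np.ceil(off / resolution - 1e-9)))
        out[a:b] = True
    return out


def stage_bin_mask(hyp: Hypnogram, stages, duration: float,
                   resolution: float = 0.1) -> np.ndarray:
    """Bins whose epoch belongs to the analysed stages (agreement restriction)."""
    stages = set(stages)
    n = int(round(duration / resolution))
    centers = (np.arange(n) + 0.5) * resolution
    return np.array([hyp.stage_at(t) in stages for t in centers])


def agreement_stats(bin_a: np.ndarray, bin_b: np.ndarray) -> AgreementResult:
    """All agreement statistics from two binary timelines (A = reference)."""
    a = np.asarray(bin_a, dtype=bool)
    b = np.asarray(bin_b, dtype=bool)
    if a.size == 0 or a.shape != b.shape:
        raise ValidationError("timelines must be non-empty and equally long")
    tp = int(np.sum(a & b))
    fp = int(np.sum(~a & b))
    fn = int(np.sum(a & ~b))
    tn = int(np.sum(~a & ~b))
    n = a.size

    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan

    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else np.nan

    # adjusted G-mean (Batuwita & Palade): weight specificity by the
    # proportion of negative examples N_n
    if tp + fn and sens > 0:
        gm = np.sqrt(sens * spec)
        n_n = (tn + fp) / n
        agm = (gm + spec * n_n) / (1.0 + n_n)
    else:
        agm = 0.0

    return AgreementResult(TP=tp, FP=fp, FN=fn, TN=tn,
                           sensitivity=sens, specificity=spec, precision=prec,
                           kappa=kappa, adjusted_gmean=agm, matthews=mcc,
                           kappa_label=landis_koch_label(kappa))


def landis_koch_label(kappa: float) -> str:
    """Landis & Koch benchmark category for a kappa (or ICC) value."""
    if np.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def event_overlap_sets(events_a, events_b, min_overlap: float = 0.3):
    """Greedy one-to-one event matching by decreasing temporal overlap.

    Two events match iff their intersection lasts at least ``min_overlap``
    seconds (0.3 s: the shortest spindle a scorer marks).  Returns a dict
    with ``consensus`` (list of index pairs), ``only_a`` and ``only_b``
    (lists of unmatched indices).
    """
    pairs = []
    for i, ea in enumerate(events_a):
        a0, a1 = _interval(ea)
        for j, eb in enumerate(events_b):
            b0, b1 = _interval(eb)
            ov = min(a1, b1) - max(a0, b0)
            if ov >= min_overlap - 1e-12:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_a, used_b, consensus = set(), set(), []
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            consensus.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return {
        "consensus": consensus,
        "only_a": [i for i in range(len(events_a)) if i not in used_a],
        "only_b": [j for j in range(len(events_b)) if j not in used_b],
    }


def weighted_average(values, weights=None) -> float:
    """Weighted mean; used to pool per-recording statistics with the number
    of investigated sleep epochs as weights."""
    return float(np.average(np.asarray(values, dtype=float), weights=weights))


def pearson(x, y) -> float:
    """Pearson correlation coefficient."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)
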