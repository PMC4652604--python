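# Methods

## The detection model

Sleep spindles are 10–16 Hz NREM oscillations with a waxing–waning envelope,
usually 0.5–2.5 s long. The detector convolves the 100 Hz EEG with complex
Morlet wavelets

```
psi((t-b)/a) = pi^(-1/4) · exp(i·2π·f0·(t-b)/a) · exp(-((t-b)/a)²)
```

with central frequency parameter `f0 = 2`, whose two-cycle envelope
resembles a spindle. The scale–frequency map is `f = f0/a`; with `f0 = 2`
the Morlet correction term is negligible and is omitted, matching the
equation above (the kernel dilated to 14 Hz has its spectral peak at
14.0 Hz, which anchors the mapping). Kernels are truncated where the
Gaussian envelope falls below 1e-6 of its peak and L1-normalised so a
unit-amplitude sinusoid at the kernel frequency produces a steady-state CWT
magnitude of ≈ 1 in signal units; thresholds expressed in µV therefore act
uniformly across the 9–16 Hz grid.

An event is a maximal run where the envelope strictly exceeds the
spindle-activity threshold SA, kept iff it lasts ≥ 0.5 s and strictly
exceeds the spindle-peak threshold SP at least once. Ties break toward
non-detection. Event bounds are the run bounds; runs touching a clean
segment boundary are kept if they satisfy the duration inside the segment.
There is no maximum duration.

## Preprocessing

The signal is resampled to 100 Hz (polyphase, anti-aliased), giving a
0.01 s timeline. Two exclusion rules run per channel on the whole night:

* **EMG**: band-pass 19.8–45.5 Hz (−3 dB), standard deviation over 1-s
  windows stepping 0.5 s (anchored at t = 0, trailing partials dropped);
  windows with SD > 5.75 µV form exceedance fragments, each padded ±3 s, so
  one bad window excises 7 s.
* **Alpha**: high-pass 1.4 Hz; amplitude spectra on 4-s Hann windows
  (step 1 s); per-second mean amplitudes for 2–4 Hz and 8–12 Hz; a 15-s
  sliding window (step 1 s) Hann-weights the 15 values of each band and the
  whole window is excluded when alpha_activity > 1.1 × delta_activity
  (strict). Band means average linear amplitudes, and the full 15-s window
  is masked with overlapping triggers unioned.

All FIR filters are linear-phase Hamming windowed-sinc kernels whose
firwin cutoffs are solved numerically so the measured −3 dB points match
the stated edges (within ±0.2 Hz); they are applied with `mode="same"`
(zero group delay). Stage selection intersects the masks with the epochs of
interest afterwards; thresholds, scans and scoring all run on these
"clean" maximal segments only.

## Thresholds

BT summarises background amplitude: the clean signal is band-passed
5.5–18.2 Hz, one-sided amplitude spectra are taken on non-overlapping 2-s
windows (0.5 Hz bins), log10-transformed, the per-bin **median** across
windows estimates the background (robust to bursts: a single 2-s
high-amplitude event in 10 min moves BT by < 2 %), and BT is the
back-transformed mean over the 6–18 Hz bins (endpoints inclusive). Then
`SA = 55·BT` and `SP = 80·BT` (SP/SA = 1.45). Returning BT in linear
amplitude units (rather than log units) keeps it homogeneous — doubling the
signal doubles BT — and dimensionally commensurate with the CWT envelopes.

**Spectrum calibration.** The absolute scale of a windowed amplitude
spectrum is conventional, and the 55×/80× multipliers only make sense
relative to a particular pairing of spectral and CWT scalings. With the
unit-sinusoid CWT normalisation used here, the raw one-sided `2|X|/N`
convention would put 55×BT roughly an order of magnitude above the
background sigma envelope of 1/f EEG and nothing realistic would ever
cross it. The spectra are therefore scaled by `bt_spectrum_scale`
(default 0.10, config-exposed), fixed once so that on EEG-like 1/f
background SA lands at ≈ 2× the RMS of the background sigma-band CWT
envelope — the operating point at which sustained (≥ 0.5 s) background
exceedances vanish while spindles a few times above background are fully
recovered, and marginal detections sit just above the background as in
validated recordings. All threshold ratios are unaffected by this factor.

## Individual band adjustment

Envelopes are computed on the 9–16 Hz grid at 0.1 Hz (71 bins) for one
frontal and one parietal channel, each with its own thresholds. Per bin,
events are detected on that bin's envelope; an event is accepted for the
bin iff its mean envelope there strictly exceeds its mean envelope at every
other bin (dominance — so each event lands in at most one bin). Counts form
`vec_slow` (frontal) and `vec_fast` (parietal).

Comparison: the 9 Hz bin is zeroed (it aggregates everything at and below
9 Hz), both vectors are smoothed twice with a centred 0.7 Hz (7-bin) moving
average whose window shrinks at the edges, and half the grand-mean activity
is added to both before forming the antisymmetric relation

```
vec_rel[i] =  v_fast[i]/v_slow[i] − 1    if v_fast ≥ v_slow
           = −(v_slow[i]/v_fast[i] − 1)  otherwise
```

followed by one more smoothing pass. The published definition of this
relation exists only as a figure; the ratio form above reproduces all its
stated properties (sign convention, antisymmetry under channel swap,
damping by 0.5·mean_act keeping it finite at empty bins) and is isolated in
one function so it can be substituted.

Band estimation: `slow_cntr = argmin(vec_rel)`; the fast candidate is
`argmax(vec_rel)` above it, shifted to the nearest local maximum of the
smoothed parietal vector within ±1 Hz (ties to the lower frequency); the
fast band spans the zero crossings of the second derivative (central
differences) of the smoothed parietal vector flanking the centre, clamped
to the grid when a side has none. The slow band's upper edge is the highest
bin below the fast band with frontal dominance; its lower edge descends
from the centre to the first bin where vec_rel has recovered to 0.6× its
(negative) minimum — i.e. 40 % off the minimum, the cautious rule that
keeps alpha out. `stop_detect` is the highest bin below the slow band with
parietal dominance, else 9 Hz. Bands are widened symmetrically to ≥ 0.5 Hz
around their centres, and the chain
`9 ≤ stop_detect ≤ slow.lo < slow.hi < fast.lo < fast.hi ≤ 16` is enforced.
With fewer than 30 accepted events in either vector (counted after the
9 Hz zeroing, before smoothing) the estimate is unreliable and fixed
fallback bands are returned (slow 11–12.9, fast 13.1–15, stop 9 Hz) with a
source flag. Adjustment is run separately per stage selection (stage 2 vs
SWS) — slow spindles drift lower in SWS.

## Scoring and measurement

`cwt_slow`/`cwt_fast` are pointwise maxima of the envelope over each band's
0.1 Hz grid (endpoints inclusive); `cwt_all = max(slow, fast)`; `cwt_stop`
is the envelope at the single stop_detect frequency. *All* spindles:
events of `cwt_all`, kept iff mean(cwt_all) > mean(cwt_stop) over the
event. *Fast*: maximal runs where `cwt_fast` is continuously strictly
above `cwt_slow` and above SA, with the usual duration/peak rules and no
stop test. *Slow*: the mirror image plus the stop test. Fast and slow
events can therefore never overlap; a single-sample tie splits a run.

Amplitude and frequency: the raw channel is band-passed 8.7–18.5 Hz, the
event fragment is Hann-windowed, zero-padded to 10 s and Fourier
transformed (0.1 Hz grid); the height and location of the maximum peak
(searched within 9–16 Hz so events honour the frequency invariant) are the
spindle's spectral amplitude and dominant frequency. The one-sided spectrum
is scaled by `2/Σ(hann)` so a full-fragment tone of amplitude A reports
≈ A. Events are assigned to the 30-s epoch containing their onset; density
is events per epoch of the analysed stage, and activity is
count × mean amplitude × mean duration.

## Agreement statistics

Two scorings are compared on a 0.1-s binary timeline (a bin is positive iff
any event overlaps it), restricted to epochs of the analysed stage. From the
confusion counts (first scorer as reference): sensitivity, specificity,
precision; Cohen's kappa `(p_o − p_e)/(1 − p_e)`; Matthews correlation
(equal to the Pearson correlation of the timelines to 1e-10); and the
adjusted G-mean of Batuwita & Palade,
`AGm = (√(sens·spec) + spec·N_n)/(1 + N_n)` with `N_n` the negative-class
proportion, 0 when sensitivity is 0 — chosen because spindle-free signal
dominates and inflates specificity. Kappa ranges carry Landis–Koch labels.
Event-level consensus matches events one-to-one greedily by decreasing
overlap with a 0.3 s minimum intersection.

## Twin analyses

GVA follows the classical two-estimator scheme (see the module docstring of
`twinstats` for the mean-square algebra): one-way ANOVA per zygosity with
pair as factor; an F′ test of equal total variances (two-sided,
Satterthwaite df, α = 0.2) selects the combined among+within estimator GCT
when totals differ and the within-pair estimator GWT otherwise.
Prerequisites: per-zygosity normality (Lilliefors form of the
Kolmogorov–Smirnov test, since the normal parameters are estimated from the
sample) and equal MZ/DZ means (Welch t-test); a 5 % significant mean
difference aborts the genetic test, since the trait would be associated
with zygosity itself. Analyses use per-subject means over the two nights;
no multiple-testing correction is applied.

A property worth knowing: the F′ gate correlates with the GWT statistic, so
the select-then-test procedure is mildly conservative under an independent
(no familial covariance) null — simulated type-I ≈ 0.03 — while holding the
nominal ≈ 0.05 under a shared-environment null, the confound the test
actually guards against. At 32 MZ / 14 DZ pairs its power against a trait
with 80 % genetic variance is ≈ 0.7: the DZ group is small and about a
fifth of replicates route to the weaker GCT branch.

ICCs use the one-way random-effects form `(MSA − MSW)/(MSA + MSW)` for
groups of two: pair as group (night-averaged values) for within-pair
resemblance and subject as group (two nights) for stability. Significance
comes from a bootstrap null that resamples individual values with
replacement into pseudo-pairs (breaking pair structure), accepting only
positive ICCs until exactly 1000 accumulate (iteration cap 10⁶ draws); the
99th percentile of those is the P = 0.01 threshold and their median the
similarity expected by chance. Smaller samples yield higher thresholds.

## Synthetic data

The generator emulates what the detector must separate, not thalamocortical
physiology: per channel, 1/f-amplitude pink noise (random phase spectral
shaping, total SD 15 µV) plus band-limited 0.5–4 Hz delta (SD 10 µV);
Hann-enveloped sigma bursts — a slow train (11.5 Hz, frontal-weighted) and
a fast train (13.5 Hz, parietal-weighted), Poisson 3 per 30-s epoch each,
durations uniform 0.6–1.4 s (validated recordings average ≈ 0.8–1.0 s),
envelope peak 18 µV ≈ 10× the background sigma-band RMS (≈ 1.5–2 µV) —
clearly visible spindles, well above the ≥ 3× detectability condition;
Hann-enveloped 10 Hz alpha bursts (20 µV, 3 s, 0.2/epoch, posteriorly
weighted); and 20–45 Hz noise bursts (15 µV SD, 1.5 s, 0.1/epoch). Events
are placed with a 0.5 s guard and never overlap; an irresolvable density
raises an error. Everything is reproducible bit-for-bit from the seed.

What passing on this data does **not** show: performance on real EEG with
non-stationary background, K-complexes, arousals, eye movements, drifting
spindle frequency within an event, or scorer-style ambiguity. The
generator's spindles are pure windowed tones, so measured frequencies are
sharp; real spindles are broader.

Twin phenotypes follow the additive model: MZ co-twins share the genetic
value, DZ co-twins' genetic values correlate 0.5 (shared + independent
halves); shared environment per pair, unique environment per subject, night
noise per subject-night. Defaults: 32 MZ / 14 DZ pairs, trait mean 4
(a plausible spindle density), variances 0.8/0.0/0.2, night noise SD 0.1.

## Problem sizes and numerical notes

Test simulations use 10-minute two-channel recordings at 250 Hz (the scan
and full pipeline run in a few seconds), 2000 replicates for the GVA
type-I simulation, 500–2000 pairs for ICC recovery, and 1000-positive
bootstrap nulls. Convolutions use overlap-add FFT; envelope edges within
half a kernel support of a segment boundary are computed with zero padding
and flagged. Event times are seconds from recording start, half-open
`[onset, offset)`, 0-based samples. Degenerate inputs raise typed errors
(zero spectra, constant ICC samples, empty stage selections) rather than
returning NaNs.

## Known limitations

* The relation-vector formula is a faithful surrogate for a figure-only
  definition; a different published form would shift band edges slightly.
* The spectrum calibration factor is a package convention; absolute BT
  values are not comparable across detectors, only the 55/80 structure is.
* GVA p-values assume mean squares are independent scaled chi-squares;
  the Satterthwaite df for summed mean squares are approximate.
* The EDF reader requires uniform sampling rates across requested channels;
  EDF writing is out of scope.
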