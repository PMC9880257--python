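# Methods

This note documents the models, conventions and numerical choices behind
`cionacpg`, in the order the pipeline runs: the synthetic recording
model, normalization and burst detection, circular phase statistics,
seven-phase classification, tail kinematics, and cohort statistics. It
closes with what the synthetic tests do and do not establish about real
recordings.

## Synthetic recording model

The generator emulates dual-channel Ca²⁺ imaging of the bilateral MN2
pair at the canonical 0.2 s/frame rate.

**Burst timing.** The right channel is a gamma renewal process with a
configured mean interval and coefficient of variation (CV); gamma is
chosen for positivity and freely tunable dispersion, since only interval
means and the qualitative labels "sporadic"/"constant" are reported for
the regimes being emulated. A refractory floor of 5 s keeps consecutive
bursts physically separated; at the ≥40 s means of interest the induced
bias on the interval mean is below 0.5%. With probability
`coupling_prob` a right burst spawns a left burst jittered by
N(0, `sync_jitter_sd`); uncoupled stretches of the left channel are
filled from an independent renewal process with the same marginal
parameters. A coupled left burst copies the right burst's duration: a
synchronized burst is one behavioural episode seen by both cells, and
independent durations would insert ~2 s of spurious left–right peak
scatter, contradicting the near-zero phase means the synchronized
regimes are supposed to show.

**Phase defaults.** Interval means follow the reported regimes — 40 s
for the convergent II–IV regime, 55 s (V), 85 s (VI); 70 s is used for
the sporadic tail-absorption regime (VII), which has no printed mean.
Dispersions and coupling are package defaults chosen once to realize the
qualitative descriptions: CV 0.8 (I, sporadic), 0.35 (II, converging),
0.10 (III–VI, "constant intervals"), 0.70 (VII); coupling 0 for I–III,
0.4 for the "rarely synchronizes" phase IV, 1.0 for V–VII. Long bursts
(>30 s) occur with probability 0.1 per event in VI and VII, with
durations uniform on 31–45 s. Burst durations are otherwise gamma with
mean 5 s, CV 0.3.

**Indicator read-out.** An event contributes a saturating rise
1 − e^{−t/τ_r} during the burst and a first-order decay e^{−k_off(t−d)}
afterwards. The decay constants are the cited indicator rates
interpreted as s⁻¹ — k_off = 1.1 (GCaMP6s, τ ≈ 0.91 s) and 3.9 (GCaMP6f,
τ ≈ 0.26 s) — consistent with the indicator literature's convention;
the bare numbers carry no units where they are quoted, so this
interpretation is stated prominently. τ_r defaults to 0.5 s (a
GCaMP6s-like rise). Contributions sum; amplitudes are gamma with mean
1.0 ΔF/F₀ and CV 0.1; Gaussian noise with SD 0.05 ΔF/F₀ is added; the
raw trace is baseline·(1 + signal + noise) with baseline 100. Noise
level and amplitudes are invented package defaults — no noise figures
are reported for the emulated recordings.

**Tail tracks.** Early tail flicks are single-signed half-sine bending
excursions (default amplitude 40°); swim bouts are sign-alternating
sinusoids (30°) with a short ramp envelope; quiescence elsewhere.
Coordinates of the three tracked points (ocellus, mid-tail, tail tip)
are laid out so that recomputing the bending angle from the coordinates
returns the generating series, then jittered by 0.3 px of tracker-like
noise.

## Normalization and burst detection

ΔF/F₀ uses a centered rolling-percentile baseline (10th percentile,
120 s window). The window must exceed the longest burst-plus-decay by a
comfortable margin so ≥10% of every window is burst-free; 120 s covers
the 45 s worst-case long burst at ≥55% duty cycle. The trace is then
differentiated with the Savitzky–Golay first-derivative kernel (window
7 frames = 1.4 s, order 3, both config-exposed; no filter parameters are
reported for the original analysis).

Detection works on the denoised derivative, with a MAD-based noise scale
σ̂ = 1.4826·MAD:

- candidate peaks need height **and** prominence ≥ 4σ̂ (pure prominence
  admits noise peaks whose bases dip below zero — their prominence
  exceeds their height — at an unacceptable false-positive rate; a real
  burst onset rises from ~0, so the height gate does not cost recall);
- thresholds have relative floors (5% of the derivative maximum for the
  peak threshold, 10⁻³ for the zero-band ε, otherwise ε = 0.1σ̂): on
  noiseless input σ̂ collapses to zero and the smoothing filter's ripple
  sidelobes would otherwise register as events;
- onset = last sample before the peak with derivative ≤ ε; the
  **negative lobe** anchoring the offset is the derivative minimum
  between this peak and the next (a long plateau's noise crosses ±ε
  constantly; the decay trough does not), and the offset is the first
  return to ≥ −ε after it;
- peaks closer than 2 s are merged keeping the larger; overlapping event
  windows are merged only when no decay lobe (≤ −2σ̂) separates their
  peaks — that distinguishes ghost peaks (smoothing overshoot at a sharp
  plateau corner, noise on a plateau) from genuinely fused bursts, which
  are instead split at the inter-peak derivative minimum;
- a rise-significance gate: ΔF/F₀ must gain ≥ 6 noise scales within 5 s
  of onset. The onset sample sits on a local trough by construction
  (a positive derivative lobe follows a dip), which biases the measured
  rise by ~2σ; 6 absorbs that while remaining far below the ~20σ rise of
  a real burst.
- `truncated` marks events whose onset or offset hits the recording
  boundary; such events are excluded from duration statistics.

**Peak time.** The burst peak is the fluorescence maximum between onset
and offset, with ties — and near-ties within one noise scale — broken
toward the latest sample. A saturating burst is flat at its plateau, so
the raw argmax lands wherever the noise happens to peak; the
sustained-maximum end pins the peak to the plateau end, the physical
maximum of the underlying transient. (The alternative convention, peak
of the *derivative*, would time-stamp the rise instead; the fluorescence
maximum is used because intervals and phase angles are defined on it.)

At the default noise level this detector achieves per-phase recall and
precision ≥ 0.95 against generator ground truth on all seven phase
defaults, and leaves ≥ 95% of noise-only traces event-free.

## Circular phase statistics

A left peak at time t in the right cycle [tᵢ, tᵢ₊₁) maps to
360·(t − tᵢ)/(tᵢ₊₁ − tᵢ) degrees, wrapped to (−180°, 180°] (signed
angles are canonical because the synchronized regimes concentrate near
0° with small negative means; raw [0°, 360°) is available). A left peak
exactly on a right peak belongs to the cycle it starts (0°). Peaks
before the first or at/after the last right peak are discarded and
counted. Pooling across recordings concatenates angle lists without
weighting.

The Rayleigh statistic is R = |Σe^{iθ}|/n with the classical
small-sample p approximation p = exp(√(1+4n+4(n²−Rₙ²)) − (1+2n)),
Rₙ = nR. The circular mean is flagged undefined when R < 10⁻¹²
(numerical zero). Empirical type-I error at p < 0.05, n = 100, is
0.05 ± 0.02 over 2000 replicates.

Histogram bins partition (−180°, 180°] as half-open (lo, hi] intervals.

## Seven-phase classification

Windows span 10 consecutive right-channel cycles and advance by 2 —
long enough for a stable dispersion estimate, short relative to phase
durations. Features:

- mean interval (peak-to-peak, matching the interval definition) and an
  interval CV computed on **onset-to-onset** intervals: a burst's peak
  falls at its plateau end, so peak intervals mix the initiation rhythm
  with burst-duration differences, and sporadic long bursts would push a
  regular window's CV over the sporadic threshold; onset intervals
  cancel the duration term exactly;
- synchronized fraction: greedy nearest-neighbor matching of left/right
  peaks within tol = max(2 s, 5% of the window median interval), each
  burst matched at most once, normalized by right bursts in the window.
  The left matching pool is widened by one tolerance beyond the window
  edges so partners of the boundary right peaks are not lost;
- long-burst count, and the interval ratio versus the
  synchronized-regime reference.

The decision list (first match wins), with defaults cv_regular 0.25,
cv_sporadic 0.5, s_lo 0.2, s_hi 0.8, r_long 1.3: VII if synchronized and
sporadic; VI if synchronized, regular and ratio ≥ r_long (85/55 ≈ 1.55
clears 1.3 with margin on both sides); V if synchronized and regular;
IV if regular with intermediate synchrony; III if regular and
unsynchronized; II for intermediate dispersion; I for sporadic. All
thresholds are explicit package definitions — the source taxonomy never
quantifies "rarely" or "sporadic" — and are echoed into the JSON summary
for provenance.

The reference interval self-calibrates as the median right interval of
the first run of three consecutive fully-synchronized regular windows
(one qualifying window can be a fluke of intermittent synchrony). On an
isolated single-phase segment self-calibration is impossible — a pure
lengthened-interval recording would self-reference and read as phase V —
so `window_features` accepts an explicit `ref_interval`; analyses of
single regimes pass the phase-V default (55 s).

Label smoothing is a width-3 mode filter with merging of equal
neighbours; each window owns the span to the next window's start, so
segments tile the analyzed span. An optional monotone mode projects
backward transitions onto the previous label. Developmental stage
metadata is never used by the classifier.

Phase II is approximated by intermediate dispersion only: its defining
property is a *trend* (intervals converging), which a stationary window
cannot capture. Phase I/II and III/IV confusions in validation reflect
small-sample CV noise (10 intervals) and the binomial tail of the
synchrony fraction, not detection errors.

## Tail kinematics

Curvature is the signed three-point (Menger) form
κ = 4·Area(ABC)/(|AB||BC||CA|) — magnitude equal to the reciprocal
circumradius — and the bending angle at the mid-tail point is
180° minus the interior angle there. Both are signed by the z-component
of the cross product with **leftward bend positive** (the source plots
left/right traces without an explicit sign convention; ours is stated
and used consistently, so lETF deflections are positive). Frames with
any body-part likelihood below 0.9 (the usual pose-tracking convention)
or with coincident points are flagged and excluded.

Bouts are runs where |bending| exceeds a threshold (default 3× the MAD
scale of the series — valid when recordings are mostly quiescent) for
≥ 50 ms; sub-resolution flickers (< 10 ms) are discarded before runs
separated by < 0.3 s are merged, because an alternating swim dips
through zero every half beat. An epoch is a swim bout if it contains
≥ 3 sign reversals at ≥ 3 Hz (reversals counted outside a half-threshold
deadband), else an ETF sided by its extreme deflection. Beat frequency
is (reversals/2)/duration — zero-crossing counting, which is robust for
the 1–30 s bouts of interest where spectral peaks are not.

Burst–behaviour co-occurrence assigns each bout to channels whose burst
windows (widened by a 2 s lag) overlap it, yielding counts over
{L-only, R-only, both, neither} per bout type.

## Cohort statistics

Onset laterality is the channel of the earliest detected peak, with ties
within one frame flagged indeterminate and excluded (but counted).
Percentages mirror the mixed reporting precision of the stimulation
tables: integers at ≥10%, one decimal below; exact fractions are kept
internally. The stimulation-table counts used in tests and in the
acceptance script — (29, 1, 2, 2) of 34 right-side trials and (27, 3) of
30 left-side trials — are reconstructed from the printed percentages;
an enumeration test verifies each reconstruction is the unique integer
vector with those renderings. No hypothesis test is attached to the 2×4
table (none is reported for it).

## What the synthetic tests establish

Passing tests show the pipeline recovers the statistical structure the
generator puts in: renewal-process intervals, Bernoulli coupling with
Gaussian jitter, saturating-kernel bursts with additive white noise, and
ideal three-point tail geometry. Real recordings differ in ways the
generator does not emulate: photobleaching and focus drift beyond a slow
baseline, motion artifacts, correlated (shot) noise, amplitude rundown,
within-burst spike structure (visible with fast indicators as notched
bursts), interval nonstationarity within a phase, and pose-tracking
outliers. The rolling-percentile baseline, MAD-based thresholds and
likelihood gating address the generic forms of these, but quantitative
claims (e.g. recall ≥ 0.95) are statements about the emulated
conditions, not about any particular microscope.

Two further caveats. Detection of *fused* bursts — a burst rising before
its predecessor's fluorescence has decayed — is resolved by the
decay-lobe splitting rule, but peak times inside fused pairs are
ambiguous by construction (the summed trace's maximum can sit on the
overlap), so exact peak recovery is only guaranteed for isolated bursts.
And two independent oscillators sharing a period (the regular
independent regime) have a slowly drifting relative phase: their
resultant length R is wide-distributed no matter how many cycles are
pooled, so "independent ⇒ low R" is only a sharp statement for the
sporadic independent regimes.
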