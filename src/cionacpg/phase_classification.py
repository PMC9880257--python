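"""Rule-based seven-phase classification of the bilateral burst dynamics.

The developmental taxonomy distinguishes phases I-VII by interval
regularity and left-right synchrony: sporadic independent bursting (I),
converging intervals (II), regular independent oscillation (III), regular
oscillation with rare synchrony (IV), fully synchronized regular
oscillation (V), synchronized oscillation at lengthened intervals with
sporadic long bursts (VI), and synchronized but sporadic bursting during
tail absorption (VII).  Windows of consecutive right-channel cycles are
featurized (interval mean/CV, synchronized-burst fraction, long-burst
count, interval ratio versus the synchronized-regime reference) and
labeled by an ordered decision list with explicit, config-exposed
thresholds; the qualitative terms "rarely", "sporadic" and "constant"
are operationalized by those thresholds, which are package definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mode

import numpy as np

from .trace_processing import BurstTrain

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Thresholds:
    """Classifier thresholds (the taxonomy's qualitative terms made explicit).

    ``cv_regular`` bounds the interval CV of "constant interval" phases,
    ``cv_sporadic`` the CV above which bursting counts as sporadic;
    ``s_lo``/``s_hi`` bound the synchronized fraction for "rarely" vs
    "fully" synchronized; ``r_long`` is the minimum interval ratio (vs the
    synchronized-regime reference) that separates the lengthened-interval
    phase VI from phase V (85/55 ~ 1.55 clears it with margin);
    ``sync_tol_floor`` is the minimum peak-matching tolerance in seconds
    (the effective tolerance is ``max(floor, 5% of the window median
    interval)``).
    """

    cv_regular: float = 0.25
    cv_sporadic: float = 0.5
    s_lo: float = 0.2
    s_hi: float = 0.8
    r_long: float = 1.3
    sync_tol_floor: float = 2.0

    def sync_tol(self, median_interval: float) -> float:
        if not math.isfinite(median_interval):
            return self.sync_tol_floor
        return max(self.sync_tol_floor, 0.05 * median_interval)


@dataclass
class WindowFeatures:
    """Feature vector of one window of consecutive right-channel cycles."""

    t_start: float
    t_end: float
    mean_interval_L: float
    mean_interval_R: float
    cv_L: float
    cv_R: float
    sync_fraction: float
    long_burst_count: int
    interval_ratio_vs_ref: float


@dataclass
class PhaseSegment:
    """A labeled, non-overlapping stretch of the recording."""

    label: str
    t_start: float
    t_end: float
    features: WindowFeatures


# ---------------------------------------------------------------------------
# synchrony matching
# ---------------------------------------------------------------------------

def match_synchronous_bursts(train_L: BurstTrain, train_R: BurstTrain,
                             tol: float) -> tuple[list[tuple[int, int]], float]:
    """Greedy nearest-neighbor matching of left/right peak times.

    Pairs with ``|dt| <= tol`` are accepted smallest-|dt| first, each
    burst matched at most once.  Returns ``(matches, sync_fraction)``
    where matches are ``(i_L, i_R)`` index pairs and sync_fraction is
    matched pairs over the right-channel burst count (0 when the right
    train is empty).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    tl, tr = train_L.peak_times, train_R.peak_times
    if tl.size == 0 or tr.size == 0:
        return [], 0.0
    pairs = [(abs(tl[i] - tr[j]), i, j)
             for i in range(tl.size)
             for j in range(tr.size)
             if abs(tl[i] - tr[j]) <= tol]
    pairs.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        matches.append((i, j))
    return matches, len(matches) / tr.size


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _interval_stats(peaks: np.ndarray,
                    onsets: np.ndarray | None = None) -> tuple[float, float]:
    """Mean peak-to-peak interval, with CV taken on burst-onset intervals.

    Inter-burst intervals are defined peak to peak, but a burst's peak
    falls at the end of its plateau, so peak intervals mix the initiation
    rhythm with burst-duration differences; sporadic long bursts then
    read as interval outliers.  Onset intervals cancel the duration term
    and measure the rhythm's own dispersion.  When onsets are not given
    the CV falls back to the peak intervals.
    """
    if peaks.size < 2:
        return float("nan"), float("nan")
    iv = np.diff(peaks)
    m = float(np.mean(iv))
    base = np.diff(onsets) if onsets is not None and onsets.size >= 2 else iv
    bm = float(np.mean(base))
    cv = float(np.std(base, ddof=1) / bm) if base.size > 1 and bm > 0 else 0.0
    return m, cv


def window_features(train_L: BurstTrain, train_R: BurstTrain,
                    window_cycles: int = 10, step_cycles: int = 2,
                    thresholds: Thresholds | None = None,
                    ref_interval: float | None = None) -> list[WindowFeatures]:
    """Per-window features over sliding windows of right-channel cycles.

    A window spans ``window_cycles`` consecutive right intervals.  The
    reference interval for ``interval_ratio_vs_ref`` is, by default,
    self-calibrated as the median right interval of the first window that
    is fully synchronized and regular; pass ``ref_interval`` explicitly
    when analyzing an isolated segment that contains no phase-V-like
    epoch (self-calibration cannot see a regime it never visits).
    Returns an empty list when the right train has too few bursts.
    """
    if window_cycles < 5:
        raise ValueError("window_cycles must be >= 5")
    if step_cycles < 1:
        raise ValueError("step_cycles must be >= 1")
    th = thresholds or Thresholds()
    tr = train_R.peak_times
    tl = train_L.peak_times
    if tr.size < window_cycles + 1:
        return []
    feats: list[WindowFeatures] = []
    for i0 in range(0, tr.size - window_cycles, step_cycles):
        r_peaks = tr[i0:i0 + window_cycles + 1]
        t_start, t_end = float(r_peaks[0]), float(r_peaks[-1])
        l_sel = [k for k, t in enumerate(tl) if t_start <= t <= t_end]
        l_peaks = tl[l_sel]
        sub_L = BurstTrain("L", [train_L.events[k] for k in l_sel])
        r_sel = list(range(i0, i0 + window_cycles + 1))
        sub_R = BurstTrain("R", [train_R.events[k] for k in r_sel])
        r_onsets = np.array([e.onset_time for e in sub_R.events])
        l_onsets = np.array([e.onset_time for e in sub_L.events])
        mean_R, cv_R = _interval_stats(r_peaks, r_onsets)
        mean_L, cv_L = _interval_stats(l_peaks, l_onsets)
        tol = th.sync_tol(float(np.median(np.diff(r_peaks))))
        # matching pool widened by one tolerance so the partners of the
        # boundary R peaks are not lost to the window edge
        lm = [k for k, t in enumerate(tl) if t_start - tol <= t <= t_end + tol]
        match_L = BurstTrain("L", [train_L.events[k] for k in lm])
        _, sync = match_synchronous_bursts(match_L, sub_R, tol)
        n_long = sum(ev.is_long for ev in sub_L.events + sub_R.events)
        feats.append(WindowFeatures(
            t_start=t_start, t_end=t_end,
            mean_interval_L=mean_L, mean_interval_R=mean_R,
            cv_L=cv_L, cv_R=cv_R, sync_fraction=sync,
            long_burst_count=int(n_long),
            interval_ratio_vs_ref=float("nan")))
    if ref_interval is None:
        ref_interval = _self_calibrate_reference(feats, train_R, th,
                                                 window_cycles, step_cycles)
    for f in feats:
        f.interval_ratio_vs_ref = (f.mean_interval_R / ref_interval
                                   if ref_interval and math.isfinite(ref_interval)
                                   else float("nan"))
    return feats


def _self_calibrate_reference(feats: list[WindowFeatures], train_R: BurstTrain,
                              th: Thresholds, window_cycles: int,
                              step_cycles: int) -> float:
    # first run of 3 consecutive fully-synchronized regular windows: a
    # single qualifying window can be a fluke of intermittent synchrony
    tr = train_R.peak_times
    ok = [f.sync_fraction >= th.s_hi and f.cv_R <= th.cv_regular for f in feats]
    need = min(3, len(ok))
    for k in range(len(ok) - need + 1):
        if all(ok[k:k + need]):
            i0 = k * step_cycles
            return float(np.median(np.diff(tr[i0:i0 + window_cycles + 1])))
    return float("nan")


# ---------------------------------------------------------------------------
# the decision list
# ---------------------------------------------------------------------------

def classify_window(f: WindowFeatures, thresholds: Thresholds | None = None) -> str:
    """Label one window I..VII by the ordered decision list (first match wins).

    VII: synchronized and sporadic; VI: synchronized, regular, lengthened
    intervals; V: synchronized and regular; IV: regular with intermediate
    synchrony; III: regular and unsynchronized; II: intermediate
    dispersion; I: sporadic.  Windows with undefined features are
    labeled ``"unclassified"``.
    """
    th = thresholds or Thresholds()
    cv, sync = f.cv_R, f.sync_fraction
    ratio = f.interval_ratio_vs_ref
    if not (math.isfinite(cv) and math.isfinite(sync)):
        return UNCLASSIFIED
    if sync >= th.s_hi and cv > th.cv_sporadic:
        return "VII"
    if (sync >= th.s_hi and cv <= th.cv_regular
            and math.isfinite(ratio) and ratio >= th.r_long):
        return "VI"
    if sync >= th.s_hi and cv <= th.cv_regular:
        return "V"
    if cv <= th.cv_regular and th.s_lo < sync < th.s_hi:
        return "IV"
    if cv <= th.cv_regular and sync <= th.s_lo:
        return "III"
    if th.cv_regular < cv <= th.cv_sporadic:
        return "II"
    return "I"


def smooth_segments(labels: list[str], windows: list[WindowFeatures],
                    monotone: bool = False) -> list[PhaseSegment]:
    """Mode-filter window labels (width 3) and merge equal neighbours.

    Each window owns the span from its start to the next window's start
    (the last window owns its full extent), so the returned segments tile
    the analyzed span without overlap.  With ``monotone=True`` any
    backward transition in developmental order (other than into
    ``unclassified``) is projected onto the previous label.
    """
    if not labels:
        return []
    if len(labels) != len(windows):
        raise ValueError("labels and windows must align")
    smoothed = _mode_filter(labels)
    if monotone:
        order = {lab: i for i, lab in
                 enumerate(("I", "II", "III", "IV", "V", "VI", "VII"))}
        out = [smoothed[0]]
        for lab in smoothed[1:]:
            prev = out[-1]
            if (lab in order and prev in order
                    and order[lab] < order[prev]):
                lab = prev
            out.append(lab)
        smoothed = out
    starts = [w.t_start for w in windows]
    ends = starts[1:] + [windows[-1].t_end]
    segments: list[PhaseSegment] = []
    for lab, t0, t1, w in zip(smoothed, starts, ends, windows):
        if segments and segments[-1].label == lab:
            segments[-1].t_end = t1
        else:
            segments.append(PhaseSegment(label=lab, t_start=t0, t_end=t1,
                                         features=w))
    return segments


def _mode_filter(labels: list[str], width: int = 3) -> list[str]:
    half = width // 2
    out = []
    for i in range(len(labels)):
        window = labels[max(0, i - half):i + half + 1]
        counts = {lab: window.count(lab) for lab in set(window)}
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append(labels[i] if labels[i] in winners else
                   mode(window))
    return out


def onset_laterality(train_L: BurstTrain, train_R: BurstTrain,
                     frame_interval: float = 0.2) -> str:
    """Channel whose first burst peak comes earlier: ``"L"``, ``"R"`` or
    ``"indeterminate"`` when both first peaks fall within one frame."""
    if train_L.n_events == 0 and train_R.n_events == 0:
        raise ValueError("no bursts in either channel")
    if train_L.n_events == 0:
        return "R"
    if train_R.n_events == 0:
        return "L"
    tl, tr = train_L.peak_times[0], train_R.peak_times[0]
    if abs(tl - tr) < frame_interval:
        return "indeterminate"
    return "L" if tl < tr else "R"
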